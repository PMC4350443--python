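EGID	Entrez Gene Identifiers
HGNC	HGNC Approved Gene Symbols
MGI	MGI Approved Gene Symbols
RGD	RGD Approved Gene Symbols
SPAC	Swiss-Prot Proteins (Accession Numbers)
SP	Swiss-Prot (Entry Names)
HGU95AV2	Affymetrix GeneChip Human Genome U95Av2
HGU133AB	Affymetrix GeneChip Human Genome U133AB
HGU133P2	Affymetrix GeneChip Human Genome U133Plus2
MGU74ABC	Affymetrix GeneChip Mouse Genome U74ABC
MG430AB	Affymetrix GeneChip Mouse Expression Set 430
MG4302	Affymetrix GeneChip Mouse Genome 430 2.0
MG430A2	Affymetrix GeneChip Mouse Genome 430A 2.0
RG230AB	Affymetrix GeneChip Rat Expression Set 230AB
RG2302	Affymetrix GeneChip Rat Genome 230 2.0
CHEBIID	Chemicals of Biological Interest (Identifiers)
CHEBI	Chemicals of Biological Interest (Names)
LMSD	LIPID MAPS Structure Database (Names)
GOAC	GO Biological Processes (Accession Numbers)
GO	GO Biological Processes (Names)
MESHPP	MeSH Phenomena and Processes (Names)
MESHD	MeSH Diseases (Names)
MESHCL	MeSH Cell Locations (Names)
GOCCACC	GO Cellular Component (Accession Numbers)
GOCCTERM	GO Cellular Component (Terms)
PFH	Named Human Protein Families
NCH	Named Human Complexes
PFM	Named Mouse Protein Families
NCM	Named Mouse Complexes
PFR	Named Rat Protein Families
NCR	Named Rat Complexes
SCHEM	Selventa Legacy Chemical Names
SDIS	Selventa Legacy Disease Names
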