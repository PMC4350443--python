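a	abundance
bp	biological process
cat	catalytic activity
sec	cell secretion
surf	cell surface expression
chap	chaperone activity
complex	complex abundance
composite	composite abundance
deg	degradation
fus	fusion
g	gene abundance
gtp	GTP bound activity
kin	kinase activity
m	microRNA abundance
act	molecular activity
path	pathology
pep	peptidase activity
phos	phosphatase activity
p	protein abundance
pmod	protein modification
rxn	reaction
ribo	ribosylation activity
r	RNA abundance
sub	substitution
tscript	transcriptional activity
tloc	translocation
tport	transport activity
trunc	truncation
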