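ligand	receptor	source
CCL19	CCR7	curated
CXCL12	CXCR4	curated
THBS2	CD36	curated
THBS1	CD36	curated
FN1	ITGA5	curated
MDK	ITGA4	curated
MDK	ITGA6	curated
FGL1	LAG3	curated
ANGPTL4	SDC4	curated
MDK	SDC4	curated
VCAM1	ITGA4	curated
CXCL13	CXCR5	curated
SYNLIG1	SYNREC1	synthetic
SYNLIG2	SYNREC2	synthetic
SYNLIG3	SYNREC3	synthetic
SYNLIG4	SYNREC4	synthetic
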