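# Synthetic variant fixture: rsID <TAB> alias (optional mutation notation)
# Hand-built fixture standing in for a dbSNP excerpt; aliases let
# DNA/protein-mutation mentions be merged under their rsID.
rs2285666	G8790A
rs12329760	p.V160M
rs11385942
rs657152
rs10490770
rs2236757
rs74956615
rs1990760	p.A946T
rs12252	c.-21T>C
rs333	delta32
rs429358	p.C130R
rs7412	p.R176C
rs1800795	-174G/C
rs1800629	-308G/A
rs5186	A1166C
rs2074192
rs4646994	ALU287bp
rs2106809
rs1799864	p.V64I
rs1024611	-2518A/G
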