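symbol	family	role	elr_positive	aliases	mouse_homolog
CXCL1	CXC	ligand	true	GRO1,GROA	Cxcl1
CXCL2	CXC	ligand	true	GRO2,GROB	Cxcl2
CXCL3	CXC	ligand	true	GRO3,GROG	Cxcl3
PF4	CXC	ligand	false	CXCL4	Pf4
CXCL5	CXC	ligand	true	ENA78	Cxcl5
CXCL6	CXC	ligand	true	GCP2
PPBP	CXC	ligand	true	CXCL7,NAP2	Ppbp
CXCL8	CXC	ligand	true	IL8
CXCL9	CXC	ligand	false	MIG	Cxcl9
CXCL10	CXC	ligand	false	IP10	Cxcl10
CXCL11	CXC	ligand	false	ITAC	Cxcl11
CXCL12	CXC	ligand	false	SDF1	Cxcl12
CXCL13	CXC	ligand	false	BLC	Cxcl13
CXCL14	CXC	ligand	false	BRAK	Cxcl14
CXCL16	CXC	ligand	false		Cxcl16
CCL2	CC	ligand	false	MCP1	Ccl2
CCL3	CC	ligand	false	MIP1A	Ccl3
CCL4	CC	ligand	false	MIP1B	Ccl4
CCL5	CC	ligand	false	RANTES	Ccl5
CCL7	CC	ligand	false	MCP3	Ccl7
CCL8	CC	ligand	false	MCP2	Ccl8
CCL11	CC	ligand	false	EOTAXIN	Ccl11
CCL13	CC	ligand	false	MCP4
CCL14	CC	ligand	false	HCC1
CCL15	CC	ligand	false	HCC2
CCL16	CC	ligand	false	HCC4
CCL18	CC	ligand	false	PARC
CCL19	CC	ligand	false	ELC	Ccl19
CCL20	CC	ligand	false	MIP3A,LARC	Ccl20
CCL21	CC	ligand	false	SLC	Ccl21a
CCL22	CC	ligand	false	MDC	Ccl22
CCL23	CC	ligand	false	MPIF1
CCL24	CC	ligand	false	EOTAXIN2	Ccl24
CCL25	CC	ligand	false	TECK	Ccl25
CCL26	CC	ligand	false	EOTAXIN3	Ccl26
CCL28	CC	ligand	false	MEC	Ccl28
XCL1	XC	ligand	false	LYMPHOTACTIN	Xcl1
XCL2	XC	ligand	false	SCM1B
CX3CL1	CX3C	ligand	false	FRACTALKINE	Cx3cl1
CXCR1	CXC	receptor	false	IL8RA	Cxcr1
CXCR2	CXC	receptor	false	IL8RB	Cxcr2
CXCR3	CXC	receptor	false	GPR9	Cxcr3
CXCR4	CXC	receptor	false	FUSIN	Cxcr4
CXCR5	CXC	receptor	false	BLR1	Cxcr5
CXCR6	CXC	receptor	false	BONZO	Cxcr6
CCR1	CC	receptor	false	CMKBR1	Ccr1
CCR2	CC	receptor	false	CMKBR2	Ccr2
CCR3	CC	receptor	false	CMKBR3	Ccr3
CCR4	CC	receptor	false	CMKBR4	Ccr4
CCR5	CC	receptor	false	CMKBR5	Ccr5
CCR6	CC	receptor	false	CMKBR6	Ccr6
CCR7	CC	receptor	false	EBI1	Ccr7
CCR8	CC	receptor	false	CMKBR8	Ccr8
CCR9	CC	receptor	false	GPR28	Ccr9
CCR10	CC	receptor	false	GPR2	Ccr10
XCR1	XC	receptor	false	GPR5	Xcr1
CX3CR1	CX3C	receptor	false	GPR13	Cx3cr1
ACKR1	CC	receptor	false	DARC	Ackr1
ACKR2	CC	receptor	false	CCBP2,D6	Ackr2
ACKR3	CXC	receptor	false	CXCR7	Ackr3
ACKR4	CC	receptor	false	CCRL1	Ackr4
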