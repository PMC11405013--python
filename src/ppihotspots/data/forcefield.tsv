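# ppihotspots heavy-atom united force-field parameters v1
# charge: e, summed hydrogen charges included; rmin_half: A; epsilon: kcal/mol
aa	atom	charge	rmin_half	epsilon
ALA	N	-0.1000	1.8240	0.1700
ALA	CA	0.1000	1.9080	0.0860
ALA	C	0.6000	1.9080	0.0860
ALA	O	-0.6000	1.6610	0.2100
ALA	CB	0.0000	1.9080	0.0860
ARG	N	-0.1000	1.8240	0.1700
ARG	CA	0.1000	1.9080	0.0860
ARG	C	0.6000	1.9080	0.0860
ARG	O	-0.6000	1.6610	0.2100
ARG	CB	0.0000	1.9080	0.0860
ARG	CG	0.0000	1.9080	0.0860
ARG	CD	0.1000	1.9080	0.0860
ARG	NE	0.0000	1.8240	0.1700
ARG	CZ	0.6000	1.9080	0.0860
ARG	NH1	0.1500	1.8240	0.1700
ARG	NH2	0.1500	1.8240	0.1700
ASN	N	-0.1000	1.8240	0.1700
ASN	CA	0.1000	1.9080	0.0860
ASN	C	0.6000	1.9080	0.0860
ASN	O	-0.6000	1.6610	0.2100
ASN	CB	0.0000	1.9080	0.0860
ASN	CG	0.5500	1.9080	0.0860
ASN	OD1	-0.5500	1.6610	0.2100
ASN	ND2	0.0000	1.8240	0.1700
ASP	N	-0.1000	1.8240	0.1700
ASP	CA	0.1000	1.9080	0.0860
ASP	C	0.6000	1.9080	0.0860
ASP	O	-0.6000	1.6610	0.2100
ASP	CB	-0.1000	1.9080	0.0860
ASP	CG	0.5500	1.9080	0.0860
ASP	OD1	-0.7250	1.6610	0.2100
ASP	OD2	-0.7250	1.6610	0.2100
CYS	N	-0.1000	1.8240	0.1700
CYS	CA	0.1000	1.9080	0.0860
CYS	C	0.6000	1.9080	0.0860
CYS	O	-0.6000	1.6610	0.2100
CYS	CB	0.1000	1.9080	0.0860
CYS	SG	-0.1000	2.0000	0.2500
GLN	N	-0.1000	1.8240	0.1700
GLN	CA	0.1000	1.9080	0.0860
GLN	C	0.6000	1.9080	0.0860
GLN	O	-0.6000	1.6610	0.2100
GLN	CB	0.0000	1.9080	0.0860
GLN	CG	0.0000	1.9080	0.0860
GLN	CD	0.5500	1.9080	0.0860
GLN	OE1	-0.5500	1.6610	0.2100
GLN	NE2	0.0000	1.8240	0.1700
GLU	N	-0.1000	1.8240	0.1700
GLU	CA	0.1000	1.9080	0.0860
GLU	C	0.6000	1.9080	0.0860
GLU	O	-0.6000	1.6610	0.2100
GLU	CB	0.0000	1.9080	0.0860
GLU	CG	-0.1000	1.9080	0.0860
GLU	CD	0.5500	1.9080	0.0860
GLU	OE1	-0.7250	1.6610	0.2100
GLU	OE2	-0.7250	1.6610	0.2100
GLY	N	-0.1000	1.8240	0.1700
GLY	CA	0.1000	1.9080	0.0860
GLY	C	0.6000	1.9080	0.0860
GLY	O	-0.6000	1.6610	0.2100
HIS	N	-0.1000	1.8240	0.1700
HIS	CA	0.1000	1.9080	0.0860
HIS	C	0.6000	1.9080	0.0860
HIS	O	-0.6000	1.6610	0.2100
HIS	CB	0.0000	1.9080	0.0860
HIS	CG	0.1000	1.9080	0.0860
HIS	ND1	-0.4000	1.8240	0.1700
HIS	CD2	0.1000	1.9080	0.0860
HIS	CE1	0.2000	1.9080	0.0860
HIS	NE2	0.0000	1.8240	0.1700
ILE	N	-0.1000	1.8240	0.1700
ILE	CA	0.1000	1.9080	0.0860
ILE	C	0.6000	1.9080	0.0860
ILE	O	-0.6000	1.6610	0.2100
ILE	CB	0.0000	1.9080	0.0860
ILE	CG1	0.0000	1.9080	0.0860
ILE	CG2	0.0000	1.9080	0.0860
ILE	CD1	0.0000	1.9080	0.0860
LEU	N	-0.1000	1.8240	0.1700
LEU	CA	0.1000	1.9080	0.0860
LEU	C	0.6000	1.9080	0.0860
LEU	O	-0.6000	1.6610	0.2100
LEU	CB	0.0000	1.9080	0.0860
LEU	CG	0.0000	1.9080	0.0860
LEU	CD1	0.0000	1.9080	0.0860
LEU	CD2	0.0000	1.9080	0.0860
LYS	N	-0.1000	1.8240	0.1700
LYS	CA	0.1000	1.9080	0.0860
LYS	C	0.6000	1.9080	0.0860
LYS	O	-0.6000	1.6610	0.2100
LYS	CB	0.0000	1.9080	0.0860
LYS	CG	0.0000	1.9080	0.0860
LYS	CD	0.0000	1.9080	0.0860
LYS	CE	0.2500	1.9080	0.0860
LYS	NZ	0.7500	1.8240	0.1700
MET	N	-0.1000	1.8240	0.1700
MET	CA	0.1000	1.9080	0.0860
MET	C	0.6000	1.9080	0.0860
MET	O	-0.6000	1.6610	0.2100
MET	CB	0.0000	1.9080	0.0860
MET	CG	0.0500	1.9080	0.0860
MET	SD	-0.1000	2.0000	0.2500
MET	CE	0.0500	1.9080	0.0860
PHE	N	-0.1000	1.8240	0.1700
PHE	CA	0.1000	1.9080	0.0860
PHE	C	0.6000	1.9080	0.0860
PHE	O	-0.6000	1.6610	0.2100
PHE	CB	0.0000	1.9080	0.0860
PHE	CG	0.0000	1.9080	0.0860
PHE	CD1	0.0000	1.9080	0.0860
PHE	CD2	0.0000	1.9080	0.0860
PHE	CE1	0.0000	1.9080	0.0860
PHE	CE2	0.0000	1.9080	0.0860
PHE	CZ	0.0000	1.9080	0.0860
PRO	N	-0.2500	1.8240	0.1700
PRO	CA	0.1000	1.9080	0.0860
PRO	C	0.6000	1.9080	0.0860
PRO	O	-0.6000	1.6610	0.2100
PRO	CB	0.0000	1.9080	0.0860
PRO	CG	0.0000	1.9080	0.0860
PRO	CD	0.1500	1.9080	0.0860
SER	N	-0.1000	1.8240	0.1700
SER	CA	0.1000	1.9080	0.0860
SER	C	0.6000	1.9080	0.0860
SER	O	-0.6000	1.6610	0.2100
SER	CB	0.2200	1.9080	0.0860
SER	OG	-0.2200	1.6610	0.2100
THR	N	-0.1000	1.8240	0.1700
THR	CA	0.1000	1.9080	0.0860
THR	C	0.6000	1.9080	0.0860
THR	O	-0.6000	1.6610	0.2100
THR	CB	0.2200	1.9080	0.0860
THR	OG1	-0.2200	1.6610	0.2100
THR	CG2	0.0000	1.9080	0.0860
TRP	N	-0.1000	1.8240	0.1700
TRP	CA	0.1000	1.9080	0.0860
TRP	C	0.6000	1.9080	0.0860
TRP	O	-0.6000	1.6610	0.2100
TRP	CB	0.0000	1.9080	0.0860
TRP	CG	0.0000	1.9080	0.0860
TRP	CD1	0.1000	1.9080	0.0860
TRP	CD2	0.0000	1.9080	0.0860
TRP	NE1	-0.2000	1.8240	0.1700
TRP	CE2	0.1000	1.9080	0.0860
TRP	CE3	0.0000	1.9080	0.0860
TRP	CZ2	0.0000	1.9080	0.0860
TRP	CZ3	0.0000	1.9080	0.0860
TRP	CH2	0.0000	1.9080	0.0860
TYR	N	-0.1000	1.8240	0.1700
TYR	CA	0.1000	1.9080	0.0860
TYR	C	0.6000	1.9080	0.0860
TYR	O	-0.6000	1.6610	0.2100
TYR	CB	0.0000	1.9080	0.0860
TYR	CG	0.0000	1.9080	0.0860
TYR	CD1	0.0000	1.9080	0.0860
TYR	CD2	0.0000	1.9080	0.0860
TYR	CE1	0.0000	1.9080	0.0860
TYR	CE2	0.0000	1.9080	0.0860
TYR	CZ	0.2200	1.9080	0.0860
TYR	OH	-0.2200	1.6610	0.2100
VAL	N	-0.1000	1.8240	0.1700
VAL	CA	0.1000	1.9080	0.0860
VAL	C	0.6000	1.9080	0.0860
VAL	O	-0.6000	1.6610	0.2100
VAL	CB	0.0000	1.9080	0.0860
VAL	CG1	0.0000	1.9080	0.0860
VAL	CG2	0.0000	1.9080	0.0860
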