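# SYBYL (TRIPOS MOL2) atom type -> GAFF type mapping used by the MOL2 reader.
# Polar-H disambiguation (hn/ho vs hc/h1/ha) is done from the bonded heavy
# atom at read time; "H" maps to the placeholder resolved there.
C.3	c3
C.2	c2
C.1	c1
C.ar	ca
C.cat	c
N.3	n3
N.2	n2
N.1	n1
N.ar	nb
N.am	n
N.pl3	n
N.4	n3
O.3	oh
O.2	o
O.co2	o
O.spc	ow
O.t3p	ow
S.3	s
S.2	s
S.O	s
S.O2	s
P.3	p
F	f
Cl	cl
Br	br
I	i
H	*H
H.spc	hw
H.t3p	hw
Zn	Zn
Mg	Mg
Ca	Ca
Na	Na
K	K
Fe	Fe
Mn	Mn
Du	du
LP	du
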