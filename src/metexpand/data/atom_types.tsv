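# metexpand radius-1 atom environment vocabulary, version 1
# code	description
C.ar	aromatic carbon
C.nit	nitrile carbon (C#N)
C.oo2	carbon with two double-bonded oxygens (CO2, carbamate-like)
C.coo	carboxyl/ester carbon (C(=O)O)
C.con	amide-like carbon (C(=O)N)
C.co	carbonyl carbon (aldehyde/ketone)
C.imn	imine carbon (C=N)
C.yne	alkyne carbon
C.ene	alkene carbon
C.h0	sp3 carbon, no heteroatom neighbour
C.h1	sp3 carbon, one single-bonded heteroatom neighbour
C.h2	sp3 carbon, two single-bonded heteroatom neighbours
C.h3	sp3 carbon, three or more single-bonded heteroatom neighbours
N.ar	aromatic nitrogen
N.oxo	nitrogen double-bonded to oxygen (nitro/nitroso)
N.nit	nitrile nitrogen
N.d	nitrogen with a double bond (imine/azo)
N.0	isolated nitrogen (ammonia)
N.p	primary amine-like nitrogen (one heavy neighbour)
N.s	secondary nitrogen (two heavy neighbours)
N.t	tertiary nitrogen (three heavy neighbours)
N.q	nitrogen with four heavy neighbours
O.ar	aromatic oxygen
O.dp	oxygen double-bonded to phosphorus (phosphoryl)
O.ds	oxygen double-bonded to sulfur (sulfoxide/sulfone)
O.dc	oxygen double-bonded to carbon (carbonyl/oxo)
O.ep	bridging oxygen bonded to phosphorus (phosphoester/anhydride)
O.ee	bridging oxygen (ether/ester)
O.p1	terminal oxygen on phosphorus
O.h	hydroxyl oxygen
O.t	terminal bare oxygen (alkoxide/carboxylate)
O.w	isolated oxygen (water/oxide)
S.ar	aromatic sulfur
S.d	sulfur with a double bond
S.e	thioether/disulfide sulfur
S.h	thiol sulfur
S.t	terminal bare sulfur (thiolate)
S.0	isolated sulfur
P.o	phosphorus with three or more oxygen neighbours (phosphate-like)
P.o1	phosphorus with one or two oxygen neighbours
P.g	phosphorus without oxygen neighbours (phosphine-like)
F.x	fluorine
Cl.x	chlorine
Br.x	bromine
I.x	iodine
H	explicit hydrogen species (proton)
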