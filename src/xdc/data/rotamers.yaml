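# Idealized side-chain internal coordinates, one (common) rotamer per
# residue type.  Each atom is placed by the NeRF construction from three
# previously placed atoms: [name, a, b, c, bond_A, angle_deg, dihedral_deg]
# places `name` at distance bond from c, angle(b, c, name), dihedral
# (a, b, c, name).  CB entries are used only when the original residue has
# no CB to inherit.  Geometry is idealized (Engh-Huber-like bonds/angles,
# extended/common chi values); placement is deterministic, unrefined.
GLY: []
ALA:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
SER:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [OG, N, CA, CB, 1.417, 110.8, 64.0]
CYS:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [SG, N, CA, CB, 1.808, 114.4, -65.0]
THR:
  - [CB, N, C, CA, 1.540, 111.5, -122.5]
  - [OG1, N, CA, CB, 1.433, 109.5, 62.0]
  - [CG2, N, CA, CB, 1.521, 110.5, -58.0]
VAL:
  - [CB, N, C, CA, 1.540, 111.5, -122.5]
  - [CG1, N, CA, CB, 1.527, 110.5, 175.0]
  - [CG2, N, CA, CB, 1.527, 110.5, 53.0]
LEU:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.530, 116.3, -65.0]
  - [CD1, CA, CB, CG, 1.521, 110.7, 175.0]
  - [CD2, CA, CB, CG, 1.521, 110.7, 53.0]
ILE:
  - [CB, N, C, CA, 1.540, 111.5, -122.5]
  - [CG1, N, CA, CB, 1.530, 110.4, -65.0]
  - [CG2, N, CA, CB, 1.521, 110.5, 173.0]
  - [CD1, CA, CB, CG1, 1.513, 113.8, 170.0]
ASN:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.516, 112.7, -65.0]
  - [OD1, CA, CB, CG, 1.231, 120.8, -60.0]
  - [ND2, CA, CB, CG, 1.328, 116.5, 120.0]
ASP:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.516, 112.7, -65.0]
  - [OD1, CA, CB, CG, 1.249, 118.4, -15.0]
  - [OD2, CA, CB, CG, 1.249, 118.4, 165.0]
GLN:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.520, 114.1, -67.0]
  - [CD, CA, CB, CG, 1.516, 112.7, 180.0]
  - [OE1, CB, CG, CD, 1.231, 120.8, -60.0]
  - [NE2, CB, CG, CD, 1.328, 116.5, 120.0]
GLU:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.520, 114.1, -67.0]
  - [CD, CA, CB, CG, 1.516, 112.7, 180.0]
  - [OE1, CB, CG, CD, 1.249, 118.4, -15.0]
  - [OE2, CB, CG, CD, 1.249, 118.4, 165.0]
LYS:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.520, 114.1, -67.0]
  - [CD, CA, CB, CG, 1.520, 111.3, 180.0]
  - [CE, CB, CG, CD, 1.520, 111.3, 180.0]
  - [NZ, CG, CD, CE, 1.489, 111.9, 180.0]
ARG:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.520, 114.1, -67.0]
  - [CD, CA, CB, CG, 1.520, 111.3, 180.0]
  - [NE, CB, CG, CD, 1.461, 112.0, 180.0]
  - [CZ, CG, CD, NE, 1.329, 124.2, 180.0]
  - [NH1, CD, NE, CZ, 1.326, 120.0, 0.0]
  - [NH2, CD, NE, CZ, 1.326, 120.0, 180.0]
MET:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.520, 114.1, -67.0]
  - [SD, CA, CB, CG, 1.803, 112.7, 180.0]
  - [CE, CB, CG, SD, 1.791, 100.8, 180.0]
PHE:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.502, 113.8, -65.0]
  - [CD1, CA, CB, CG, 1.384, 120.8, 90.0]
  - [CD2, CA, CB, CG, 1.384, 120.8, -90.0]
  - [CE1, CB, CG, CD1, 1.382, 120.8, 180.0]
  - [CE2, CB, CG, CD2, 1.382, 120.8, 180.0]
  - [CZ, CG, CD1, CE1, 1.382, 120.0, 0.0]
TYR:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.502, 113.8, -65.0]
  - [CD1, CA, CB, CG, 1.384, 120.8, 90.0]
  - [CD2, CA, CB, CG, 1.384, 120.8, -90.0]
  - [CE1, CB, CG, CD1, 1.382, 120.8, 180.0]
  - [CE2, CB, CG, CD2, 1.382, 120.8, 180.0]
  - [CZ, CG, CD1, CE1, 1.382, 120.0, 0.0]
  - [OH, CD1, CE1, CZ, 1.376, 119.9, 180.0]
HIS:
  - [CB, N, C, CA, 1.530, 110.5, -122.5]
  - [CG, N, CA, CB, 1.497, 113.8, -65.0]
  - [ND1, CA, CB, CG, 1.371, 122.7, -70.0]
  - [CD2, CA, CB, CG, 1.356, 131.2, 110.0]
  - [CE1, CB, CG, ND1, 1.319, 109.3, 180.0]
  - [NE2, CB, CG, CD2, 1.374, 107.2, 180.0]
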