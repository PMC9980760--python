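# Default infection ICD-10 code/prefix list (one per line, # comments).
#
# This list is a documented reconstruction, not a published standard: it is
# seeded from the three chapters that dominate hospital infection coding
# (respiratory J, infectious/parasitic A-B, genitourinary N) plus common
# infection codes from other chapters used in implicit-sepsis code lists.
# Replace it with a locally validated list for production surveillance.
# Explicit sepsis codes (A40, A41, R57.2) are kept in a separate list and
# are removed from this set at load time.
#
# Certain infectious and parasitic diseases (A00-B99)
A0
A1
A2
A3
# A4x minus the explicit sepsis codes A40/A41
A42
A43
A44
A46
A48
A49
A5
A6
A7
A8
A9
B0
B1
B2
B3
B4
B5
B6
B7
B8
B9
# Respiratory infections (chapter J)
J00
J01
J02
J03
J04
J05
J06
J09
J10
J11
J12
J13
J14
J15
J16
J17
J18
J20
J21
J22
J36
J39.0
J39.1
J65
J69
J85
J86
# Genitourinary infections (chapter N)
N10
N12
N15.1
N15.9
N30
N34
N39.0
N41
N45
N49
N61
N70
N71
N72
N73
N74
N75
N76
# Skin and soft tissue
L01
L02
L03
L04
L05
L08
# Nervous system
G00
G01
G02
G03
G04
G06
G07
# Circulatory
I33
I38
I40.0
# Digestive and peritoneum
K35
K57.0
K57.2
K61
K63.0
K65
K80.0
K80.3
K81.0
K83.0
# Bone and joint
M00
M01
M86
# Eye/ear
H60
H66
H70
# Other
O85
O86
T81.4
T82.6
T82.7
T83.5
T84.5
T85.7
R65.0
R65.1
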