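l3_code
ABT
AFG
AGE
AGS
AGW
ALA
ALG
ALU
ARI
ARK
ASK
AUT
BAL
BGM
BOL
BOR
BRC
BZC
BZE
BZL
BZN
BZS
CAL
CHC
CHN
CLC
CLM
CLN
CLS
CNT
CNY
COL
COR
COS
CPP
CUB
CZE
DEL
DEN
ECU
ETH
FIN
FLA
FRA
GEO
GER
GRB
GRC
GUA
HAW
HON
IDA
ILL
IND
INI
IOW
IRE
IRN
ITA
JAM
JAP
KAN
KAZ
KEN
KOR
KTY
LAB
LAT
LOU
MAI
MAN
MAS
MDG
MIC
MIN
MNT
MON
MOR
MRY
MSI
MSO
MXC
MXE
MXG
MXI
MXN
MXP
MXS
MXT
MYA
NAT
NBR
NCA
NDA
NEB
NEP
NET
NEV
NFL
NIC
NOR
NSC
NSW
NTA
NUN
NWG
NWH
NWJ
NWM
NWT
NWY
NZN
NZS
OFS
OHI
OKL
ONT
ORE
PAK
PAN
PEI
PEN
PER
PHI
POL
POR
QLD
QUE
RHO
RUC
RUE
RUN
RUS
RUW
SAS
SCA
SDA
SIC
SOA
SPA
SRL
SUM
SWE
SWI
TAI
TAN
TAS
TEN
TEX
THA
TUR
TVL
UTA
VEN
VER
VIC
VIE
VRG
WAS
WAU
WDC
WIS
WVA
WYO
YUK
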