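# enzyme<TAB>prototype (first-described enzyme of the isoschizomer family)
AatII	AatII
AflII	AflII
AflIII	AflIII
AgeI	AgeI
ApaI	ApaI
ApoI	ApoI
AvrII	AvrII
BamHI	BamHI
BglII	BglII
BsaI	Eco31I
BsrGI	BsrGI
BstXI	BstXI
ClaI	ClaI
DdeI	DdeI
DraI	AhaIII
EagI	EagI
EcoRI	EcoRI
EcoRV	EcoRV
FseI	FseI
HincII	HincII
HindIII	HindIII
HpaI	HpaI
KpnI	KpnI
MfeI	MfeI
MluI	MluI
NcoI	NcoI
NdeI	NdeI
NheI	NheI
NotI	NotI
NsiI	AvaIII
PacI	PacI
PmlI	PmaCI
PstI	PstI
PvuII	PvuII
SacI	SacI
SalI	SalI
ScaI	ScaI
SmaI	SmaI
SpeI	SpeI
SphI	SphI
StuI	StuI
XbaI	XbaI
XhoI	XhoI
XmaI	SmaI
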