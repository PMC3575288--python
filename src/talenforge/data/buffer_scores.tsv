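# enzyme<TAB>buffer<TAB>raw activity (0-100, rescaled to [0,9] on load)
# illustrative activities in PCR buffers; 0 = no activity
BamHI	standard	100
BamHI	thermopol	75
BamHI	phusion	50
BamHI	crimson	75
EcoRI	standard	100
EcoRI	thermopol	100
EcoRI	phusion	25
EcoRI	crimson	50
EcoRV	standard	75
EcoRV	thermopol	50
EcoRV	phusion	25
EcoRV	crimson	50
HindIII	standard	75
HindIII	thermopol	50
HindIII	phusion	0
HindIII	crimson	25
KpnI	standard	50
KpnI	thermopol	25
KpnI	phusion	0
KpnI	crimson	25
NcoI	standard	100
NcoI	thermopol	75
NcoI	phusion	50
NcoI	crimson	75
NsiI	standard	75
NsiI	thermopol	100
NsiI	phusion	50
NsiI	crimson	75
PstI	standard	100
PstI	thermopol	75
PstI	phusion	25
PstI	crimson	50
PvuII	standard	100
PvuII	thermopol	100
PvuII	phusion	75
PvuII	crimson	100
SacI	standard	50
SacI	thermopol	25
SacI	phusion	0
SacI	crimson	25
SalI	standard	25
SalI	thermopol	50
SalI	phusion	0
SalI	crimson	25
SmaI	standard	50
SmaI	thermopol	0
SmaI	phusion	0
SmaI	crimson	25
SpeI	standard	75
SpeI	thermopol	50
SpeI	phusion	25
SpeI	crimson	50
XbaI	standard	75
XbaI	thermopol	100
XbaI	phusion	50
XbaI	crimson	75
XhoI	standard	100
XhoI	thermopol	75
XhoI	phusion	50
XhoI	crimson	75
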