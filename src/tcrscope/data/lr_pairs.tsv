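ligand	receptor	class
LGALS9	HAVCR2	inhibitory
PVR	TIGIT	inhibitory
PVR	CD96	inhibitory
NECTIN2	TIGIT	inhibitory
CD274	PDCD1	inhibitory
PDCD1LG2	PDCD1	inhibitory
CEACAM1	HAVCR2	inhibitory
LGALS3	LAG3	inhibitory
CD80	CTLA4	inhibitory
CD86	CTLA4	inhibitory
TNFRSF14	BTLA	inhibitory
CD80	CD28	stimulatory
CD86	CD28	stimulatory
ICOSLG	ICOS	stimulatory
TNFSF9	TNFRSF9	stimulatory
TNFSF4	TNFRSF4	stimulatory
CD70	CD27	stimulatory
TNFSF14	TNFRSF14	stimulatory
CD40LG	CD40	stimulatory
IL7	IL7R	stimulatory
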