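# Conserved fingerprint motif segments of the TAAR family (human, mouse,
# zebrafish), one row per protein, aligned ungapped segments.
# Columns: label, group, fingerprint_1 (11-mer), fingerprint_2 (13-mer),
# fingerprint_3 (14-mer).
label	group	fingerprint_1	fingerprint_2	fingerprint_3
TAAR1_HUMAN	human	SISHFKQLHTP	SMVRSAEHCWYFG	DPFLHYIIPPTLND
TAAR1_MOUSE	mouse	SISHFKQLHTP	SMVRTVERCWYFG	DPFLGYVIPPSLND
TAAR2_HUMAN	human	SISYFKQLHTP	SMIRSVENCWYFG	DPFLNFSTPVVLFD
TAAR2_MOUSE	mouse	SISYFKQLHTP	SMVRSVENCWYFG	DPFLNFSTPAVLFD
TAAR5_HUMAN	human	AVSYFKALHTP	STIRSVESCWFFG	DSLLHFITPPLVFD
TAAR5_MOUSE	mouse	AVSYFKVLHTP	STVRSVESCWFFG	DSLLNFITPPLVFD
TAAR6_HUMAN	human	SILHFKQLHSP	SMVRTVESCWYFG	DAFMGFITPACIYE
TAAR6_MOUSE	mouse	SILHFKQLHSP	SMVRSIESCWYFG	DAFMGFITPAYIYE
TAAR8_HUMAN	human	SVLHFKQLHSP	SMVRTVESCWYFG	DAFMGFLTPAYIYE
TAAR8_MOUSE	mouse	SVLHFKQLHSP	SMVRSIESCWYFG	DAFMGFITPAYVYE
TAAR8B_MOUSE	mouse	SVLHFKQLHSP	SMVRSIESCWYFG	DAFVGFITPAYVYE
TAAR8C_MOUSE	mouse	SVLHFKQLHSP	SMVRSIESCWYFG	DAFMGFITPAYVYE
TAAR9_HUMAN	human	AILHFKQLHTP	STVRSVESCWYFG	DAYMNFITPPYVYE
TAAR9_MOUSE	mouse	AILHFKQLHTP	STVRSVESCWYFG	DAYMNFITPAYVYE
TAAR13C_DANRE	fish	SIAHFKQLQTP	SMIRSVDGCWYYG	DPYINFSTPYALFD
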