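BEGIN IONS
TITLE=11
PEPMASS=490.391100
CHARGE=1+
RTINSECONDS=261.000
86.095700 1
132.101200 1
323.273700 1
341.283900 1
END IONS
BEGIN IONS
TITLE=12
PEPMASS=490.390600
CHARGE=1+
RTINSECONDS=300.600
86.095900 1
132.101800 1
323.273500 1
341.284100 1
END IONS
BEGIN IONS
TITLE=13
PEPMASS=490.390800
CHARGE=1+
RTINSECONDS=309.600
86.095600 1
132.101000 1
END IONS
BEGIN IONS
TITLE=14
PEPMASS=476.373500
CHARGE=1+
RTINSECONDS=188.400
100.074300 1
118.084800 1
323.272200 1
341.282100 1
458.362400 1
END IONS
BEGIN IONS
TITLE=15
PEPMASS=476.375100
CHARGE=1+
RTINSECONDS=225.000
100.071400 1
118.081900 1
323.272300 1
341.283100 1
458.365000 1
END IONS
BEGIN IONS
TITLE=16
PEPMASS=476.374600
CHARGE=1+
RTINSECONDS=237.000
72.077600 1
118.083100 1
323.269000 1
341.279800 1
END IONS
BEGIN IONS
TITLE=17
PEPMASS=476.373500
CHARGE=1+
RTINSECONDS=276.000
72.070400 1
118.086200 1
323.273400 1
341.283600 1
458.362400 1
END IONS
BEGIN IONS
TITLE=18
PEPMASS=476.373500
CHARGE=1+
RTINSECONDS=286.200
72.072000 1
118.086300 1
END IONS
BEGIN IONS
TITLE=19
PEPMASS=462.357800
CHARGE=1+
RTINSECONDS=180.000
86.059300 1
104.068900 1
END IONS
BEGIN IONS
TITLE=20
PEPMASS=462.359200
CHARGE=1+
RTINSECONDS=207.000
58.059900 1
104.065200 1
END IONS
BEGIN IONS
TITLE=21
PEPMASS=462.359000
CHARGE=1+
RTINSECONDS=216.000
86.059400 1
104.070000 1
323.273400 1
341.283700 1
END IONS
BEGIN IONS
TITLE=22
PEPMASS=462.356700
CHARGE=1+
RTINSECONDS=252.000
58.063800 1
104.070000 1
323.273400 1
341.284400 1
END IONS
BEGIN IONS
TITLE=23
PEPMASS=462.358300
CHARGE=1+
RTINSECONDS=258.000
58.063800 1
104.070000 1
END IONS
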