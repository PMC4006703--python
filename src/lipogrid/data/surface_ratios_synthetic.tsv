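# Surface-to-core lipid ratios per lipoprotein size class.
# SYNTHETIC stand-in table: constructed to emulate published size-class
# ratios (seven lipoprotein classes plus nascent VLDL); the transcribed
# originals are not shipped with this package.  Ratios decline with size
# because surface scales with r^2 and core with r^3.
# columns: core_radius_nm	fc_per_core	pl_per_core
core_radius_nm	fc_per_core	pl_per_core
1.2	0.55	1.60
2.0	0.42	1.10
3.5	0.30	0.75
5.0	0.22	0.55
9.0	0.12	0.30
15.0	0.085	0.20
25.0	0.060	0.14
40.0	0.045	0.10
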