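>od1_seed_1
TPPNACRLCRHTAKELHGWDKFGCPRCDLCRACQ
>od1_seed_2
TPPNSCRLCRHSAKELHGFDKFGCPRCDLCRSCQ
>od1_seed_3
TAPNACKLCRHTAKEMHGWDKFGCPRCELCRACQ
>od1_seed_4
TPPNACRICRHTSKELHGWDKYGCPRCDLCRACE
>od1_seed_5
TPPDACRLCKHTAKELHGWEKFGCPRCDVCRACQ
>od1_seed_6
SPPNACRLCRHTAKDLHGWDKFGCPQCDLCKACQ
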