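# Published per-condition averages for dihydrofolate reductase from E. coli
# (EcDHFR) and M. profunda (MpDHFR) at the four growth-condition states
# (T = 279 or 310 K; P = 1 or 220 bar), 50-ns MD, block errors over 10-ns
# intervals.  Columns: protein-averaged MSF of heavy atoms, apparent volume
# per heavy atom, interior-water count, hydrogen-bond population, and
# pair-averaged continuous hydrogen-bond lifetime.
protein	temperature_K	pressure_bar	MSF_A2	Vapp_per_NHA_A3	N_w_in	N_HB	tau_HB_ps
EcDHFR	279	1	0.65 ± 0.02	17.38 ± 0.02	1.96 ± 0.31	107 ± 2	27.7 ± 3.4
MpDHFR	279	1	0.76 ± 0.08	17.73 ± 0.04	3.25 ± 0.30	103 ± 2	30.6 ± 3.7
EcDHFR	279	220	0.71 ± 0.11	17.55 ± 0.01	2.08 ± 0.31	105 ± 1	25.5 ± 2.7
MpDHFR	279	220	0.83 ± 0.04	17.77 ± 0.03	3.28 ± 0.40	104 ± 1	22.5 ± 1.8
EcDHFR	310	1	0.93 ± 0.07	17.87 ± 0.02	2.36 ± 0.37	106 ± 1	11.6 ± 1.2
MpDHFR	310	1	1.39 ± 0.15	18.26 ± 0.02	4.21 ± 0.32	101 ± 2	11.2 ± 0.6
EcDHFR	310	220	1.04 ± 0.14	17.82 ± 0.01	2.47 ± 0.36	104 ± 1	11.2 ± 1.1
MpDHFR	310	220	1.49 ± 0.16	18.25 ± 0.01	3.26 ± 0.42	101 ± 2	11.1 ± 1.1
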