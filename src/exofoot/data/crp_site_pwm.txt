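crp_site	22	0.5
A	550	550	550	30	30	30	30	910	220	220	220	340	220	340	30	30	910	30	910	150	150	150
C	150	150	150	30	30	30	30	30	220	340	220	220	220	220	30	910	30	910	30	150	150	150
G	150	150	150	30	910	30	910	30	220	220	220	220	340	220	30	30	30	30	30	150	150	150
T	150	150	150	910	30	910	30	30	340	220	340	220	220	220	910	30	30	30	30	550	550	550
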