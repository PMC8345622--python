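sample	gender	age	preop_stage	preop_grade	tnm_after_rc	response
good1	Male	71	T2	G2/3	T0 N0	Responder
good2	Female	68	T2	G2/3	T0 N0	Responder
good3	Male	74	T2	G3	Tcis N0	Responder
good4	Male	67	T2	G2/3	T0 N0	Responder
good5	Female	69	T2	G3	T0 N0	Responder
good6	Male	56	T2	G2	Tis N0	Responder
good7	Male	46	T2	G3	T0 N0	Responder
good8	Male	64	T2	G2/3	T0 N1	Responder
good9	Male	63	T2	G3	T0 N0	Responder
good10	Male	70	T4	G3	T0 N0	Responder
good11	Male	69	T2	G3	T0 N0	Responder
good12	Male	63	T2	G2	T1 N0	Responder
good13	Male	58	T1/2	G3	Tcis N0	Responder
good14	Male	60	T2	G3	T0 N0	Responder
good15	Male	59	T2	G3	T0 N0	Responder
good16	Female	70	T2	G3	Tis N0	Responder
good17	Male	69	T2	G3	T0 N0	Responder
good18	Female	73	T2	G3	T0 N0	Responder
good19	Male	59	T2	G3	T0 N0	Responder
bad1	Male	58	T2	G3	T4a N1	Non-Responder
bad2	Male	71	T2	G3	T3a N0	Non-Responder
bad3	Male	74	T2	G3	T3 N0	Non-Responder
bad4	Male	61	T2	G3	T3b N2	Non-Responder
bad5	Female	63	T2	G2/3	T3a N2	Non-Responder
bad6	Male	65	T2	G3	T2b N0	Non-Responder
bad7	Male	60	T2	G3	T3b N0	Non-Responder
bad8	Male	64	T1/2	G3	T2b N0	Non-Responder
bad9	Male	74	T2	G2	T3a N0	Non-Responder
bad10	Male	58	T2	G3	T3a N0	Non-Responder
bad11	Male	50	T2	G2/3	T4a N2	Non-Responder
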