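family	superfamily	block	total_kb	consensus_bp	reported_copies
RLC_BARE1	Copia	class1_high_copy	623043	8630	72195
RLG_Sabrina	Gypsy	class1_high_copy	407047	8030	50691
RLG_BAGY2	Gypsy	class1_high_copy	240798	8630	27902
RLG_WHAM	Gypsy	class1_high_copy	167138	9450	17687
RLG_Surya	Gypsy	class1_high_copy	163300	14470	11285
RLC_Maximus	Copia	class1_high_copy	110928	14400	7703
RLG_BAGY1	Gypsy	class1_high_copy	102843	14400	7142
DTC_Balduin	CACTA	class1_high_copy	70688	11740	6021
RLG_Haight	Gypsy	class1_high_copy	57185	13080	4372
DTC_Caspar	CACTA	class1_high_copy	54465	11568	4708
DTT_Thalos	Mariner	mariner	2865	163	17574
DTT_Pan	Mariner	mariner	716	123	5822
DTT_Athos	Mariner	mariner	394	81	4868
DTT_Icarus	Mariner	mariner	555	117	4747
DTT_Hades	Mariner	mariner	392	108	3627
DTT_SAF	Mariner	mariner	177	85	2087
DTT_Eos	Mariner	mariner	506	326	1552
DTT_Oleus	Mariner	mariner	231	150	1540
DTT_Pluto	Mariner	mariner	328	274	1197
DTT_Stolos	Mariner	mariner	205	274	749
DTH_Thorne	Harbinger	harbinger	716	273	2624
DTH_Kerberos	Harbinger	harbinger	594	285	2086
DTH_Xumet	Harbinger	harbinger	591	376	1571
DTH_Rong	Harbinger	harbinger	1218	1227	993
DTT_Marimom	Harbinger	harbinger	2024	2129	951
DTH_Orpheus	Harbinger	harbinger	183	272	674
DTH_Xenon	Harbinger	harbinger	203	312	650
DTH_Xian	Harbinger	harbinger	650	1161	560
DTH_Kong	Harbinger	harbinger	489	2119	231
DTH_Tibone	Harbinger	harbinger	187	1037	180
DTH_Zong	Harbinger	harbinger	278	2396	116
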