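antibody,stimulation,titration1,titration2,titration3,chosen_index,transcription_uncertain
CD56,none,0.05,0.425,0.8,1,0
CD161,none,0.125,1.0625,2,1,0
CD117 (c-kit),none,0.25,0.625,1,1,0
CD16,none,0.025,0.2125,0.4,1,0
TIGIT (VSTM3),none,0.125,1.0625,2,1,0
CD335 (NKp46),none,0.05,0.425,0.8,1,0
CD294 (CRTH2),none,0.5,1.25,2,2,0
CD127 (IL-7Ra),none,0.05,0.425,0.8,1,0
CD196 (CCR6),none,0.0125,0.106,0.2,1,0
CD314 (NKG2D),pma_iono,0.0625,0.53125,1,2,0
CD336 (NKp44),none,0.5,1.25,2,2,0
CD94,none,0.025,0.2125,0.4,1,0
KLRG1 (MAFA),none,0.1,0.3,0.5,1,0
CD183 (CXCR3),none,0.05,0.425,0.8,1,0
TCR g/d,none,0.05,0.425,0.8,2,0
CD45,none,0.01,0.055,0.1,1,0
TCR Va24-Ja18 (iNKT cell),none,0.5,1.25,2,1,0
TCR a/b,none,0.015,0.1275,0.24,1,0
CD8a,none,0.025,0.2125,0.4,1,0
CD3,none,0.0125,0.106,0.2,1,0
CD4,none,0.025,0.2125,0.4,1,0
CD138 (Syndecan-1),none,0.05,0.425,0.8,2,0
CD14,none,0.025,0.2125,0.4,1,0
CD206 (MMR),none,0.25,0.625,1,1,0
HLA-DR,none,0.0125,0.106,0.2,2,0
CD45RA,none,0.03125,0.2656,0.5,1,0
CD45RO,none,0.125,1.0625,2,1,0
CD25,pma_iono,0.025,0.2125,0.4,1,0
CD223 (LAG-3),pma_iono,0.125,1.0625,2,1,0
CX3CR1,none,0.0625,0.53125,1,1,0
TSLPR (TSLP-R),none,0.5,1.25,2,1,0
CD49b,none,0.025,0.2125,0.4,1,0
CD38,pma_iono,0.05,0.425,0.8,1,0
CD57 Recombinant,none,0.025,0.2125,0.4,1,1
CD49a,none,0.025,0.2125,0.4,1,0
CD278 (ICOS),pma_iono,0.0625,0.53125,1,1,0
CD357 (GITR),pma_iono,0.5,1.25,2,1,0
CD39,pma_iono,0.0125,0.10625,0.2,1,0
CD69,pma_iono,0.025,0.2125,0.4,1,0
CD279 (PD-1),pma_iono,0.125,1.0625,2,1,0
CD152 (CTLA-4),pma_iono,0.25,0.625,1,1,0
CD107a (LAMP-1),pma_iono,0.0625,0.53125,1,1,0
CD95 (Fas),pma_iono,0.125,1.0625,2,1,0
CD134 (OX40),pma_iono,0.125,1.0625,2,1,0
CD137L (4-1BB Ligand),pma_iono,0.5,1.25,2,1,0
CD40,lps_ifng,0.025,0.2125,0.4,1,0
CD137 (4-1BB),pma_iono,0.125,1.0625,2,2,0
CD194 (CCR4),none,0.0125,0.10625,0.2,2,0
CD27,none,0.005,0.0425,0.08,2,0
CD28,none,0.03125,0.2656,0.5,1,0
GARP (LRRC32),none,0.125,0.375,0.5,1,0
CD122 (IL-2Rb),none,0.0625,0.53125,1,1,0
CD184 (CXCR4),none,0.5,1.25,2,1,0
CD49d,pma_iono,0.0125,0.10625,0.2,1,0
CD274 (B7-H1 PD-L1),pma_iono,0.0625,0.53125,1,1,0
CD120b,lps_ifng,0.01,0.255,0.5,2,0
CD80,lps_ifng,0.25,0.625,1,2,0
CD32/Fcg RII,lps_ifng,0.0125,0.10625,0.2,2,0
CD11b,lps_ifng,0.0125,0.10625,0.2,3,0
CD64 (FCGR1A),lps_ifng,0.0125,0.10625,0.2,2,0
CD86,lps_ifng,0.005,0.0425,0.08,2,0
CD163,lps_ifng,0.0625,0.53125,1,2,0
CD197 (CCR7),none,0.5,1.25,2,1,0
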