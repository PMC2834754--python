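family_id,family_name,ppi_class,pdb_pp_complex,n_inhibitors,source,affinity_nM,affinity_kind,planarity,eccentricity,ss_class_pair,gap_volume,gap_index,hb_per_100A2,salt_bridges,asa_mean_side,h_asa_percent,rmsd_unbound,pocket_volume,n_segments,pct_charged_residues,pdb_unbound,pdb_ligand_complexes
1,BclXL/Bak,I,1bxl,8,PubMed,340,KD,3.60,0.75,H/H,2892,1.75,0.05,0,825,45.6,2.3,97,5,,,
2,MDM2/p53,I,1ycr,3,PubMed,600,KD,2.99,0.86,H/H,786,0.60,0.34,1,660,54.2,1.9,351,3,,,
2,MDM2/p53,I,1ycq,3,PubMed,600,KD,2.14,0.62,H/H,1286,1.38,0.39,1,455,65.7,1.8,215,2,,,
3,XIAP BIR3/CASPASE 9,I,1nw9,2,PubMed,20,KD,2.32,0.78,S/S,3567,1.79,0.78,0,241,100.0,2.4,244,2,,,
4,XIAP BIR3/SMAC,I,1g73,5,PubMed,420,KD,2.18,0.73,S/S,3500,5.35,0.88,0,472,88.9,2.3,140,3,,,
5,ZipA/FtsZ,I,1f47,4,PubMed,20000,KD,2.76,0.75,S/H,3503,3.24,0.09,0,541,39.2,0.9,0,5,,,
6,Chagasin/Papain,II,3e1z,1,PDB,0.036,Ki,3.00,0.89,C/C,4286,2.26,0.53,0,947,55.4,0.4,279,9,,,
7,E2/E1,II,1tue,1,PubMed,,missing,2.59,0.71,H/H,5042,2.86,0.55,3,946,32.6,1.4,202,7,,,
8,FKBP12/TGFR,II,1b6c,17,PDB,,missing,2.82,0.42,S/H,5457,3.14,0.17,0,869,57.2,0.5,387,8,,,
9,IL-2/IL-2R,II,1z92,8,PubMed,10,KD,2.40,0.86,H/C,4431,2.47,0.70,5,898,39.8,1.3,146,8,,,
10,MMP1/TIMP1,II,2j0t,1,PDB,0.40,Ki,2.76,0.55,C/C,5380,4.08,0.83,0,660,48.8,0.5,323,7,,,
11,MMP3/TIMP1,II,1oo9,1,PDB,0.22,Ki,3.02,0.78,C/C,5157,2.76,0.24,0,936,39.7,1.2,227,9,,,
12,Subtilisin/Eglin C,II,1cse,1,PDB,0.029,KD,2.67,0.65,C/S,3858,3.01,0.74,0,640,62.6,0.3,282,8,,,
12,Subtilisin/Eglin C,II,1r0r,1,PDB,0.029,KD,2.54,0.75,C/C,3763,2.99,0.78,0,630,66.3,0.3,230,9,,,
12,Subtilisin/Eglin C,II,1to2,1,PDB,0.029,KD,3.11,0.61,C/S,3277,2.25,0.74,1,728,66.4,0.3,275,8,,,
13,Thrombin/Protein C inhibitor,II,3b9f,1,PDB,,missing,3.41,0.81,C/C,5538,4.33,0.72,2,639,38.0,0.6,350,9,,,
14,Trypsin/Trypsin inhibitor,II,2uuy,3,PDB,0.02,KD,2.57,0.73,C/C,3500,3.12,1.09,1,562,70.1,0.7,154,10,,,
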