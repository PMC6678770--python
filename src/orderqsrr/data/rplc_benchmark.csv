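case_study,column_name,condition,model,pct_rmse_tr,pct_rmse_order
I,Supelcosil LC-18,"tG=10min,T=35C",MLR,8.57,59.07
I,Supelcosil LC-18,"tG=10min,T=35C",MLR-NLP,8.07,51.77
II,Xterra MS C18,"tG=20min,T=40C",MLR,11.50,25.01
II,Xterra MS C18,"tG=20min,T=40C",MLR-NLP,15.17,22.40
II,LiChrospher RP-18,"tG=20min,T=40C",MLR,13.25,30.28
II,LiChrospher RP-18,"tG=20min,T=40C",MLR-NLP,12.42,39.59
II,LiChrospher RP-18,"tG=60min,T=40C",MLR,25.60,34.11
II,LiChrospher RP-18,"tG=60min,T=40C",MLR-NLP,37.94,30.10
II,LiChrospher RP-18,"tG=120min,T=40C",MLR,42.31,153.00
II,LiChrospher RP-18,"tG=120min,T=40C",MLR-NLP,85.62,25.17
II,LiChrospher RP-18,"tG=20min,T=60C",MLR,18.45,36.12
II,LiChrospher RP-18,"tG=20min,T=60C",MLR-NLP,16.86,40.70
II,LiChrospher RP-18,"tG=20min,T=80C",MLR,18.82,35.25
II,LiChrospher RP-18,"tG=20min,T=80C",MLR-NLP,21.06,34.65
II,LiChrospher CN,"tG=20min,T=40C",MLR,39.28,195.82
II,LiChrospher CN,"tG=20min,T=40C",MLR-NLP,55.53,53.45
II,PLRP-S,"tG=20min,T=40C",MLR,20.07,69.44
II,PLRP-S,"tG=20min,T=40C",MLR-NLP,20.72,58.09
II,PLRP-S,"tG=60min,T=40C",MLR,37.92,107.94
II,PLRP-S,"tG=60min,T=40C",MLR-NLP,52.40,41.33
II,PLRP-S,"tG=20min,T=60C",MLR,21.75,94.97
II,PLRP-S,"tG=20min,T=60C",MLR-NLP,24.06,82.54
II,PLRP-S,"tG=60min,T=60C",MLR,40.11,321.65
II,PLRP-S,"tG=60min,T=60C",MLR-NLP,54.35,37.16
II,PLRP-S,"tG=20min,T=80C",MLR,22.36,137.16
II,PLRP-S,"tG=20min,T=80C",MLR-NLP,26.19,53.30
II,PLRP-S,"tG=60min,T=80C",MLR,42.60,194.56
II,PLRP-S,"tG=60min,T=80C",MLR-NLP,61.56,40.18
II,Discovery RP Amide C16,"tG=20min,T=40C",MLR,36.73,261.22
II,Discovery RP Amide C16,"tG=20min,T=40C",MLR-NLP,58.07,91.81
II,Discovery RP Amide C16,"tG=20min,T=60C",MLR,36.37,219.01
II,Discovery RP Amide C16,"tG=20min,T=60C",MLR-NLP,57.16,96.70
II,Discovery RP Amide C16,"tG=20min,T=80C",MLR,36.74,241.63
II,Discovery RP Amide C16,"tG=20min,T=80C",MLR-NLP,54.75,81.05
II,Discovery HS F5-3,"tG=20min,T=40C",MLR,12.81,34.00
II,Discovery HS F5-3,"tG=20min,T=40C",MLR-NLP,13.84,28.12
II,Chromolith,"tG=20min,T=40C",MLR,20.82,43.81
II,Chromolith,"tG=20min,T=40C",MLR-NLP,24.36,28.55
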