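# 10-5 montage subset, 128 electrodes, unit-sphere head frame (x right, y front, z up)
# head radius scale: 95 mm
AF1	-0.209170	0.904819	0.370878
AF10h	0.604391	0.728140	-0.323301
AF2	0.222788	0.902626	0.368281
AF3	-0.389395	0.887815	0.245268
AF4	0.404395	0.880143	0.248623
AF5	-0.527815	0.846515	0.069453
AF6	0.532467	0.843636	0.068970
AF7	-0.620076	0.775350	-0.119742
AF8	0.620326	0.775159	-0.119684
AF9h	-0.601859	0.729008	-0.326057
AFF10	0.645679	0.556880	-0.522478
AFF1h	-0.130558	0.807804	0.574810
AFF2h	0.151941	0.802591	0.576854
AFF3h	-0.394887	0.787031	0.473969
AFF4h	0.409880	0.783333	0.467320
AFF5h	-0.598059	0.753948	0.271824
AFF6h	0.604936	0.751255	0.263946
AFF9	-0.637108	0.565607	-0.523624
AFp10	0.402826	0.770865	-0.493456
AFp2	0.152812	0.973233	0.171655
AFp3h	-0.197294	0.973570	0.115051
AFp9	-0.388499	0.778403	-0.493110
AFz	0.002623	0.915822	0.401576
C1	-0.371708	-0.102635	0.922659
C2	0.390044	-0.099645	0.915389
C3	-0.706876	-0.125802	0.696060
C4	0.720988	-0.117092	0.682983
C5	-0.927952	-0.159047	0.337058
C6	0.934162	-0.143011	0.326939
CCP1h	-0.176726	-0.272702	0.945728
CCP2h	0.194217	-0.270369	0.942964
CCP3h	-0.527029	-0.287828	0.799622
CCP4h	0.542543	-0.279435	0.792189
CCP5h	-0.799023	-0.310907	0.514684
CCP6h	0.808667	-0.296690	0.507969
CP1	-0.326425	-0.434692	0.839339
CP2	0.351645	-0.431251	0.830884
CP3	-0.618606	-0.457546	0.638732
CP4	0.637648	-0.446439	0.627771
CP5	-0.818335	-0.478616	0.318205
CP6	0.831488	-0.460056	0.311412
CPP1h	-0.139481	-0.578371	0.803761
CPP2h	0.168909	-0.570531	0.803719
CPP3h	-0.427282	-0.589187	0.685776
CPP4h	0.452850	-0.576249	0.680341
CPP5h	-0.654281	-0.604904	0.453880
CPP6h	0.671302	-0.591312	0.446881
CPz	0.003504	-0.429705	0.902963
Cz	0.003983	-0.091066	0.995837
F1	-0.314606	0.651404	0.690432
F2	0.335604	0.654987	0.677025
F3	-0.595220	0.629189	0.499834
F4	0.606623	0.635512	0.477633
F5	-0.784679	0.584687	0.205963
F6	0.791456	0.580704	0.190737
F7	-0.847627	0.512395	-0.137767
F8	0.846108	0.514567	-0.139004
FC1	-0.375357	0.286639	0.881445
FC2	0.386023	0.293400	0.874587
FC3	-0.708119	0.267286	0.653548
FC4	0.717488	0.273238	0.640743
FC5	-0.929019	0.224309	0.294293
FC6	0.929583	0.233006	0.285628
FCC1h	-0.192299	0.095987	0.976631
FCC2h	0.200019	0.098460	0.974832
FCC3h	-0.564119	0.079309	0.821876
FCC4h	0.574513	0.086343	0.813928
FCC5h	-0.853964	0.049200	0.518001
FCC6h	0.860135	0.059601	0.506573
FCz	0.004053	0.295142	0.955445
FFC1h	-0.170550	0.482775	0.858977
FFC2h	0.193085	0.483520	0.853772
FFC3h	-0.514883	0.472593	0.715228
FFC4h	0.529008	0.480202	0.699684
FFC5h	-0.785977	0.438882	0.435458
FFC6h	0.792168	0.446070	0.416523
FFT10h	0.883951	0.314677	-0.345846
FFT7h	-0.920283	0.386647	0.059862
FFT8h	0.919853	0.388688	0.052832
FFT9h	-0.883063	0.313628	-0.349051
FT10	0.848138	0.144844	-0.509590
FT7	-0.976104	0.170633	-0.134558
FT8	0.973730	0.183483	-0.134845
FT9	-0.848255	0.146972	-0.508786
FTT10h	0.942981	-0.020270	-0.332229
FTT7h	-0.994568	0.009979	0.103605
FTT8h	0.994640	0.023070	0.100794
FTT9h	-0.942426	-0.020688	-0.333773
Fp1	-0.329991	0.940726	-0.078359
Fp2	0.330899	0.940402	-0.078426
Fpz	0.001272	0.999811	-0.019408
Fz	0.003526	0.660786	0.750566
Iz	0.000037	-0.981579	-0.191059
O1	-0.252329	-0.964666	0.075827
O2	0.256398	-0.963610	0.075607
Oz	0.000929	-0.991960	0.126546
P1	-0.251075	-0.706414	0.661771
P10	0.655879	-0.660278	-0.365863
P2	0.275926	-0.695760	0.663161
P3	-0.480960	-0.714878	0.507570
P4	0.498504	-0.703519	0.506513
P5	-0.637048	-0.722449	0.268769
P6	0.642647	-0.718535	0.265919
P7	-0.701950	-0.711819	-0.024101
P8	0.706832	-0.706954	-0.024575
P9	-0.654257	-0.661036	-0.367395
PO3	-0.321642	-0.888450	0.327418
PO4	0.324496	-0.889716	0.321103
PO7	-0.489979	-0.871377	0.024946
PO8	0.495193	-0.868443	0.024285
POO1	-0.118910	-0.950848	0.285917
POO10	0.359029	-0.893437	-0.269942
POO9	-0.358549	-0.893838	-0.269250
POz	0.001891	-0.896107	0.443835
PPO10h	0.586307	-0.791854	-0.170913
PPO9h	-0.584408	-0.793017	-0.172019
Pz	0.002804	-0.700597	0.713552
T10	0.859117	-0.164286	-0.484695
T7	-0.976571	-0.185874	-0.108447
T8	0.978884	-0.172815	-0.109187
T9	-0.860682	-0.158608	-0.483808
TP10	0.795203	-0.434097	-0.423333
TP7	-0.876639	-0.475591	-0.072917
TP8	0.880320	-0.468673	-0.073370
TP9	-0.795524	-0.432188	-0.424683
TTP10h	0.900784	-0.328016	-0.284592
TTP7h	-0.934488	-0.334507	0.121806
TTP8h	0.937680	-0.325139	0.122640
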