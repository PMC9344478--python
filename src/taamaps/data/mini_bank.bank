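# pseudoatom parameter bank

TYPE O_water O
SIG O H H
PVAL 6.3
KAPPA 0.985
KPRIME 1.1
PLM 1 0 0.1
PLM 2 0 -0.05
CORE 0 29.101782368896803 1961.3220091246744
VAL 2 8.59825388171951 155.82251744148462
DEFRAD 1 2 8.59825388171951
DEFRAD 2 2 8.59825388171951
DEFRAD 3 3 8.59825388171951
DEFRAD 4 4 8.59825388171951
FRAME H H +1

TYPE H_hydroxyl H
SIG H O
PVAL 0.85
KAPPA 1.15
KPRIME 1.2
PLM 1 0 0.12
VAL 0 3.7794522557008836 2.148061595902897
DEFRAD 1 1 3.7794522557008836
DEFRAD 2 2 3.7794522557008836
DEFRAD 3 2 3.7794522557008836
DEFRAD 4 3 3.7794522557008836
FRAME O * +1

TYPE O_carboxylate O
SIG O C
PVAL 6.35
KAPPA 0.982
KPRIME 1.08
PLM 1 0 -0.08
PLM 2 0 0.06
CORE 0 29.101782368896803 1961.3220091246744
VAL 2 8.59825388171951 155.82251744148462
DEFRAD 1 2 8.59825388171951
DEFRAD 2 2 8.59825388171951
DEFRAD 3 3 8.59825388171951
DEFRAD 4 4 8.59825388171951
FRAME C * +1

TYPE N_amide N
SIG N C C H
PVAL 5.2
KAPPA 1.0
KPRIME 1.05
PLM 1 0 0.06
PLM 2 0 -0.04
CORE 0 25.32233011319592 1292.114899537086
VAL 2 7.369931898616723 72.09352624650352
DEFRAD 1 2 7.369931898616723
DEFRAD 2 2 7.369931898616723
DEFRAD 3 3 7.369931898616723
DEFRAD 4 4 7.369931898616723
FRAME H C +1

TYPE N_ammonium N
SIG N C H H H
PVAL 5.3
KAPPA 1.005
KPRIME 1.05
PLM 3 2+ 0.08
CORE 0 25.32233011319592 1292.114899537086
VAL 2 7.369931898616723 72.09352624650352
DEFRAD 1 2 7.369931898616723
DEFRAD 2 2 7.369931898616723
DEFRAD 3 3 7.369931898616723
DEFRAD 4 4 7.369931898616723
FRAME C H +1

TYPE C_alpha_gly C
SIG C C H H N
PVAL 4.05
KAPPA 1.01
KPRIME 1.0
PLM 3 2+ 0.12
CORE 0 21.542877857495036 795.6119422600904
VAL 2 6.141609915513936 28.97277128604983
DEFRAD 1 2 6.141609915513936
DEFRAD 2 2 6.141609915513936
DEFRAD 3 3 6.141609915513936
DEFRAD 4 4 6.141609915513936
FRAME N C +1

TYPE C_alpha C
SIG C C C H N
PVAL 4.05
KAPPA 1.01
KPRIME 1.0
PLM 3 2+ 0.12
CORE 0 21.542877857495036 795.6119422600904
VAL 2 6.141609915513936 28.97277128604983
DEFRAD 1 2 6.141609915513936
DEFRAD 2 2 6.141609915513936
DEFRAD 3 3 6.141609915513936
DEFRAD 4 4 6.141609915513936
FRAME N C +1

TYPE C_sp3 C
SIG C C C H H
PVAL 4.1
KAPPA 1.01
KPRIME 1.0
PLM 3 2+ 0.12
CORE 0 21.542877857495036 795.6119422600904
VAL 2 6.141609915513936 28.97277128604983
DEFRAD 1 2 6.141609915513936
DEFRAD 2 2 6.141609915513936
DEFRAD 3 3 6.141609915513936
DEFRAD 4 4 6.141609915513936
FRAME C C +1

TYPE C_amide C
SIG C C N O
PVAL 3.75
KAPPA 1.005
KPRIME 0.95
PLM 2 0 -0.2
PLM 3 2+ 0.1
CORE 0 21.542877857495036 795.6119422600904
VAL 2 6.141609915513936 28.97277128604983
DEFRAD 1 2 6.141609915513936
DEFRAD 2 2 6.141609915513936
DEFRAD 3 3 6.141609915513936
DEFRAD 4 4 6.141609915513936
FRAME O N +1

TYPE C_carboxyl C
SIG C C O O
PVAL 3.7
KAPPA 1.005
KPRIME 0.95
PLM 2 0 -0.22
PLM 3 2+ 0.1
CORE 0 21.542877857495036 795.6119422600904
VAL 2 6.141609915513936 28.97277128604983
DEFRAD 1 2 6.141609915513936
DEFRAD 2 2 6.141609915513936
DEFRAD 3 3 6.141609915513936
DEFRAD 4 4 6.141609915513936
FRAME O O +1

TYPE H_alkyl H
SIG H C
PVAL 0.9
KAPPA 1.13
KPRIME 1.2
PLM 1 0 0.1
VAL 0 3.7794522557008836 2.148061595902897
DEFRAD 1 1 3.7794522557008836
DEFRAD 2 2 3.7794522557008836
DEFRAD 3 2 3.7794522557008836
DEFRAD 4 3 3.7794522557008836
FRAME C * +1

TYPE H_ammonium H
SIG H N
PVAL 0.7
KAPPA 1.18
KPRIME 1.25
PLM 1 0 0.13
VAL 0 3.7794522557008836 2.148061595902897
DEFRAD 1 1 3.7794522557008836
DEFRAD 2 2 3.7794522557008836
DEFRAD 3 2 3.7794522557008836
DEFRAD 4 3 3.7794522557008836
FRAME N * +1
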