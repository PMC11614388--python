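metabolite,n,overall_mean,overall_sd,bsa_mean,bsa_sd,pa_mean,pa_sd,p_value,q_value
b_DL.Lactic.Acid,12,7768093932.0,566966988.5,7315358105.8,237880097.3,8220829758.2,398345524.3,0.002,0.064
b_D..Glutamine,12,92514878.8,9477866.2,99910567.8,6363882.4,85119189.7,5084875.9,0.002,0.064
a_Acetyl.L.carnitine,12,21534366.5,5136659.2,25486005.2,4313399.0,17582727.8,1401821.0,0.004,0.085
b_L.Serine,12,8927932.4,1999447.4,10439581.3,1620380.1,7416283.5,827833.2,0.009,0.13
b_X4.Oxoproline,12,5158697.7,2093379.7,6584223.3,1496000.9,3733172.0,1589279.7,0.026,0.3
b_X3.Hydroxy.2.methyl.4.pyrone.tent.,12,112324855.5,18985842.0,122558080.8,13194171.3,102091630.2,19173036.1,0.065,0.6
a_Adipic.acid.tent.,12,463554.3,1036466.7,0.0,0.0,927108.7,1359286.8,0.074,0.6
a_D..Pyroglutamic.Acid,12,287577957.7,32240216.1,302927531.8,25661286.0,272228383.5,32600385.7,0.093,0.6
b_L.Arabinose.or.isomer.,12,427996608.9,18980682.8,437653974.3,18029045.8,418339243.5,15611025.3,0.093,0.6
b_L.Tyrosine,12,85928933.3,296055668.3,345898.5,293093.1,171511968.0,418627435.0,0.13,0.7
b_Sodium.lauryl.sulfate,12,22598.3,76220.7,0.0,0.0,45196.5,107496.4,0.2,0.7
b_Tridecanoic.acid,12,113734.1,302240.1,0.0,0.0,227468.2,412217.0,0.2,0.7
a_Leucine,12,27980174.9,7729502.5,30862636.3,2851217.9,25097713.5,10167075.1,0.2,0.7
b_Glutaric.acid.tent.,12,440497616.4,19061443.4,448877445.2,22010672.2,432117787.7,12097256.5,0.2,0.7
a_PEG.n5.tent.,12,344189.2,776660.6,4541.3,11123.9,683837.0,1024721.6,0.2,0.7
a_L.Serine,12,390966.4,346737.4,527905.0,409596.4,254027.8,227430.6,0.2,0.7
b_D..Glucose.or.isomer.,12,5354625351.9,372775074.5,5219148234.7,282140339.8,5490102469.2,426687091.4,0.2,0.7
b_AICA.ribonucleotide,12,64660392.8,5188450.2,63405196.7,3409871.4,65915588.8,6619333.0,0.2,0.7
b_neuraminic.acid.tent.,12,23066967.0,2864562.7,24475099.5,3412576.8,21658834.5,1283781.1,0.2,0.7
a_Betaine,12,3612697.5,2636694.6,2762143.5,2827681.0,4463251.5,2358539.4,0.3,>0.9
a_DL.Arginine,12,3821072.9,7222808.1,2199664.0,5388054.4,5442481.8,8912410.1,0.3,>0.9
a_L.Threonine,12,5270710.2,5478082.2,6513108.5,5492782.8,4028311.8,5669696.2,0.4,>0.9
a_Pantothenic.acid,12,22359057.0,26015488.1,28020428.8,25119049.5,16697685.2,27947862.2,0.4,>0.9
b_L.Leucine,12,6646608.2,3705017.3,7399027.0,3879174.6,5894189.3,3713895.4,0.4,>0.9
b_Crotonic.acid,12,16108825.9,23803380.1,23947637.5,26242912.3,8270014.3,20257315.3,0.4,>0.9
b_Succinic.acid,12,407804.1,869276.7,109080.2,267190.7,706528.0,1173394.8,0.5,>0.9
a_L.Lysine,12,24416825.1,28518776.0,34566558.7,36434829.3,14267091.5,14648122.2,0.5,>0.9
b_Pyridoxal.tent.,12,777482.7,1211214.3,598171.7,398509.7,956793.7,1729598.9,0.5,>0.9
b_X2.C.Methyl.D.erythritol4.phosphate.tent.,12,643051857.5,148219463.1,606454245.0,172899107.7,679649470.0,123382309.5,0.5,>0.9
b_X2.Methylsuccinic.acid.tent.,12,287186644.6,143335650.3,264074195.0,155198662.0,310299094.2,140821055.1,0.5,>0.9
b_Pyruvic.acid.tent.,12,150010045.5,9715420.7,147364165.0,6350912.8,152655926.0,12268697.7,0.5,>0.9
a_Niacinamide,12,1384815.1,2023883.3,1614438.5,2373808.4,1155191.7,1802752.7,0.5,>0.9
a_X6.Methoxyquinoline.tent.,12,7956394.3,26119894.0,15246370.2,37028395.4,666418.3,1516716.5,0.5,>0.9
a_L..Methionine,12,788318.3,1316035.4,642601.0,747341.7,934035.5,1789080.3,0.5,>0.9
b_X4.Hydroxyquinoline,12,2294626.8,5198100.9,3743521.2,7079171.4,845732.5,2071613.1,0.6,>0.9
a_X2.2.6.6.Tetramethyl.4.piperidinol.tent.,12,3349971.7,5949414.1,4474480.0,7959519.7,2225463.3,3388416.0,0.6,>0.9
a_N.N.Diethylethanolamine.tent.,12,3251751.6,3370326.9,2444947.7,2152767.5,4058555.5,4335133.4,0.6,>0.9
b_L.Isoleucine,12,7328303.6,7854185.2,8665141.0,7496666.0,5991466.2,8673233.1,0.7,>0.9
a_X6.Methylquinoline.tent.,12,385.0,699.5,274.2,671.6,495.8,772.0,0.8,>0.9
a_Hypoxanthine,12,38073.7,83225.3,44836.3,109826.1,31311.0,55377.5,0.8,>0.9
b_p.Toluenesulfonic.acid.tent.,12,3372499.5,6572551.8,3393943.8,5259090.6,3351055.2,8208375.3,0.8,>0.9
b_Urocanic.acid.tent.,12,1399.0,2534.9,1818.7,2821.3,979.3,2398.9,0.8,>0.9
a_Pyridoxal.tent.,12,1928431.0,3031562.9,2203965.7,3922077.7,1652896.3,2157295.3,0.8,>0.9
b_X3.Methyl.2.oxovaleric.acid,12,1101172.5,3039252.9,282158.3,278456.3,1920186.7,4316724.3,0.8,>0.9
b_L.Methionine,12,747354.3,822900.9,676740.7,845132.3,817968.0,873813.0,0.8,>0.9
b_L.Tryptophan,12,198603.2,296935.2,272248.2,407584.4,124958.2,121792.6,0.8,>0.9
a_Indole.3.acrylic.acid,12,2553283.9,3140722.0,2083026.7,2110564.8,3023541.2,4088504.8,0.8,>0.9
b_X4.Dodecylbenzenesulfonic.acid.tent.,12,10280591.5,7701423.0,8121727.2,4928645.2,12439455.8,9747256.3,0.8,>0.9
a_N.Acetylputrescine,12,386960.3,468563.5,391056.2,550659.6,382864.3,423966.5,0.9,>0.9
a_D..Proline,12,661884.2,1149335.2,957007.0,1564926.8,366761.3,498103.3,0.9,>0.9
a_X4.Aminonicotinic.acid.or.isomer.,12,126303.5,225453.7,94034.3,196574.4,158572.7,265864.7,>0.9,>0.9
a_Choline,12,174331021.6,21492889.5,171722892.2,20170821.4,176939151.0,24353435.2,>0.9,>0.9
b_Acetoacetic.acid,12,319609159.2,14397923.5,321712028.7,13338036.2,317506289.7,16356781.0,>0.9,>0.9
a_Isoleucine,12,30943808.3,15505575.1,29880732.5,15885905.7,32006884.2,16548594.4,>0.9,>0.9
b_L.Phenylalanine,12,9511810.9,5608112.4,10045803.3,6593135.4,8977818.5,5003823.0,>0.9,>0.9
a_Creatine,12,137229.8,326719.4,112430.3,275396.9,162029.2,396888.8,>0.9,>0.9
b_D..Fructose.or.isomer.,12,1376324172.0,124013739.0,1382734756.2,112787783.2,1369913587.8,144965454.4,>0.9,>0.9
b_Folic.acid,12,3351599.5,3207090.2,4052769.5,4167729.0,2650429.5,2019416.2,>0.9,>0.9
b_Propylparaben.or.isomer.,12,255003.3,618051.8,190425.0,466444.1,319581.7,782812.0,>0.9,>0.9
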