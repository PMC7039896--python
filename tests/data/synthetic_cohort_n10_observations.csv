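subject_id,observer,observation,reference,actual_deg
S001,1,1,c1,557.8085867
S001,1,1,tip,599.2538457
S002,1,1,c1,534.4683779
S002,1,1,tip,574.3818702
S003,1,1,c1,508.5542952
S003,1,1,tip,544.4370589
S004,1,1,c1,492.8789264
S004,1,1,tip,529.4235352
S005,1,1,c1,590.4028004
S005,1,1,tip,633.8954135
S006,1,1,c1,546.7780521
S006,1,1,tip,587.5897275
S007,1,1,c1,567.6880229
S007,1,1,tip,609.9554999
S008,1,1,c1,518.6820987
S008,1,1,tip,558.0625749
S009,1,1,c1,666.1656503
S009,1,1,tip,718.5683859
S010,1,1,c1,555.4148664
S010,1,1,tip,596.2613822
S001,2,1,c1,564.2584133
S001,2,1,tip,606.0654966
S002,2,1,c1,532.6547888
S002,2,1,tip,572.4675231
S003,2,1,c1,503.6864118
S003,2,1,tip,539.3199898
S004,2,1,c1,486.2398325
S004,2,1,tip,522.4338333
S005,2,1,c1,580.8812143
S005,2,1,tip,623.8388515
S006,2,1,c1,554.1707776
S006,2,1,tip,595.3967535
S007,2,1,c1,578.2416641
S007,2,1,tip,621.1044544
S008,2,1,c1,526.9816323
S008,2,1,tip,566.8255692
S009,2,1,c1,665.0851399
S009,2,1,tip,717.4259123
S010,2,1,c1,544.6103756
S010,2,1,tip,584.8580325
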