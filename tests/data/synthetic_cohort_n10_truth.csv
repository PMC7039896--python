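subject_id,A_true_mm,B_true_mm,shortfall_mm,actual_linear_c1_mm,actual_angle_c1_deg,actual_angle_tip_deg
S001,9.230675738,6.580509746,0.3439683563,26.45603164,557.997799,599.453672
S002,9.277735318,6.612524937,0.6412736984,26.1587263,543.3674765,583.7760589
S003,9.619733401,7.128200644,0.09965584953,26.70034415,504.575497,540.2545374
S004,9.099447293,6.941502027,1.309329907,25.49067009,499.5301337,536.4274967
S005,8.413848402,6.838666614,0.08055828185,26.71944172,571.447678,613.8741085
S006,9.234326843,6.582403456,0.5534916218,26.24650838,550.6744016,591.7043904
S007,8.904562745,6.647244639,0.2318312076,26.56816879,567.3711652,609.6207576
S008,8.629771434,6.777345276,1.528484882,25.27151512,521.6817724,561.2295821
S009,8.301277929,6.081704371,0.2366123081,26.56338769,659.993858,712.041217
S010,9.545282572,6.561389174,0.5736259378,26.22637406,540.831571,580.8700187
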