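subject_id,ear,observer,observation,method,A_mm,B_mm
S001,L,1,1,software-3d,9.108026299,6.744316349
S002,L,1,1,software-3d,8.622943531,7.030679836
S003,L,1,1,software-3d,10.17766834,6.87408694
S004,L,1,1,software-3d,8.543422272,7.287303582
S005,L,1,1,software-3d,8.527827515,6.497077742
S006,R,1,1,software-3d,8.706136005,6.594582068
S007,L,1,1,software-3d,8.871537581,6.734310475
S008,L,1,1,software-3d,8.641007699,6.614061959
S009,R,1,1,software-3d,8.878670507,5.568703857
S010,R,1,1,software-3d,9.293808981,6.90086045
S001,L,1,2,software-3d,9.631011448,6.549807267
S002,L,1,2,software-3d,9.467726724,6.162285675
S003,L,1,2,software-3d,9.990622345,7.125215313
S004,L,1,2,software-3d,9.422833441,6.877522809
S005,L,1,2,software-3d,8.862522115,6.606788572
S006,R,1,2,software-3d,8.963775117,6.585155065
S007,L,1,2,software-3d,8.546861002,6.910245336
S008,L,1,2,software-3d,8.555312809,6.929421574
S009,R,1,2,software-3d,8.574534232,6.22493741
S010,R,1,2,software-3d,9.525394476,6.180467052
S001,L,2,1,software-3d,9.1596148,6.7295921
S002,L,2,1,software-3d,9.395665357,6.479525182
S003,L,2,1,software-3d,10.42581039,7.751647555
S004,L,2,1,software-3d,9.166578805,6.972333006
S005,L,2,1,software-3d,9.119566227,6.207881476
S006,R,2,1,software-3d,9.396176723,7.340518238
S007,L,2,1,software-3d,8.952069009,7.218079299
S008,L,2,1,software-3d,9.1682512,6.765891094
S009,R,2,1,software-3d,7.999641781,6.608823734
S010,R,2,1,software-3d,9.845513273,6.768604469
S001,L,2,2,software-3d,8.757331106,6.913780369
S002,L,2,2,software-3d,9.35190133,6.613213179
S003,L,2,2,software-3d,9.502434158,7.075642207
S004,L,2,2,software-3d,9.460618434,6.876455849
S005,L,2,2,software-3d,8.233964661,6.99562827
S006,R,2,2,software-3d,9.586662894,6.73907886
S007,L,2,2,software-3d,9.030405204,6.397163406
S008,L,2,2,software-3d,8.571169568,6.970203085
S009,R,2,2,software-3d,8.749865055,6.028690285
S010,R,2,2,software-3d,9.283617307,6.664311206
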