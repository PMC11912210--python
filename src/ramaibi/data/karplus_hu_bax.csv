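# Default Karplus parameter table (Hz; theta0 in degrees).
# 3J values: self-consistent parameters of Hu & Bax (J. Am. Chem. Soc. 1997,
# 119, 6360), J = A cos^2(theta + theta0) + B cos(theta + theta0) + C with
# theta the backbone dihedral named in depends_on.
# 1J(N,CA): psi-dependent relation of Wirmer & Schwalbe (J. Biomol. NMR 2002,
# 23, 47); no parameter uncertainties are published for it.
# Edit or replace this file to use a different parametrization.
coupling_name,A,B,C,theta0,depends_on,s_A,s_B,s_C
"3J(HN,HA)",7.09,-1.42,1.55,-60.0,phi,0.11,0.09,0.06
"3J(HN,C')",4.29,-1.01,0.00,180.0,phi,0.13,0.10,0.07
"3J(HA,C')",3.72,-2.18,1.28,120.0,phi,0.14,0.11,0.08
"3J(HN,CB)",3.06,-0.74,0.13,60.0,phi,0.12,0.09,0.06
"3J(C,C')",1.36,-0.93,0.60,0.0,phi,0.10,0.08,0.05
"1J(N,CA)",-0.98,1.70,9.51,0.0,psi,,,
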