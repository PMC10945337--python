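# Mass energy-absorption coefficients for liquid water.
# source: NIST standard reference tables (Hubbell & Seltzer), mu_en/rho in cm^2/g.
# Valid interpolation range for the sphere self-dose model: 20-2000 keV (log-log linear).
energy_keV,mu_en_over_rho_cm2_per_g
20,0.5503
30,0.1557
40,0.06947
50,0.04223
60,0.03190
80,0.02597
100,0.02546
150,0.02764
200,0.02967
300,0.03192
400,0.03279
500,0.03299
600,0.03284
800,0.03206
1000,0.03103
1250,0.02965
1500,0.02833
2000,0.02608
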