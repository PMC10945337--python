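# Per-patient organ absorbed doses per administered activity (Gy/GBq = mGy/MBq)
# for one PSMA-617 cycle labeled with Tb-161 and, intra-individually, Lu-177.
# Six-patient mCRPC cohort; four regions per patient and nuclide.
patient_id,region_id,nuclide,dose_Gy_per_GBq
patient1,kidneys,Tb161,0.638
patient1,liver,Tb161,0.290
patient1,parotid,Tb161,0.793
patient1,submandibular,Tb161,0.718
patient1,kidneys,Lu177,0.666
patient1,liver,Lu177,0.199
patient1,parotid,Lu177,0.398
patient1,submandibular,Lu177,0.309
patient2,kidneys,Tb161,0.537
patient2,liver,Tb161,0.167
patient2,parotid,Tb161,0.312
patient2,submandibular,Tb161,0.223
patient2,kidneys,Lu177,0.492
patient2,liver,Lu177,0.138
patient2,parotid,Lu177,0.150
patient2,submandibular,Lu177,0.190
patient3,kidneys,Tb161,0.942
patient3,liver,Tb161,0.196
patient3,parotid,Tb161,0.197
patient3,submandibular,Tb161,0.205
patient3,kidneys,Lu177,0.906
patient3,liver,Lu177,0.069
patient3,parotid,Lu177,0.146
patient3,submandibular,Lu177,0.112
patient4,kidneys,Tb161,0.483
patient4,liver,Tb161,0.090
patient4,parotid,Tb161,0.338
patient4,submandibular,Tb161,0.446
patient4,kidneys,Lu177,0.674
patient4,liver,Lu177,0.125
patient4,parotid,Lu177,0.703
patient4,submandibular,Lu177,0.664
patient5,kidneys,Tb161,0.284
patient5,liver,Tb161,0.051
patient5,parotid,Tb161,0.227
patient5,submandibular,Tb161,0.194
patient5,kidneys,Lu177,0.252
patient5,liver,Lu177,0.037
patient5,parotid,Lu177,0.217
patient5,submandibular,Lu177,0.178
patient6,kidneys,Tb161,0.974
patient6,liver,Tb161,0.093
patient6,parotid,Tb161,0.338
patient6,submandibular,Tb161,0.446
patient6,kidneys,Lu177,0.278
patient6,liver,Lu177,0.049
patient6,parotid,Lu177,0.387
patient6,submandibular,Lu177,0.259
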