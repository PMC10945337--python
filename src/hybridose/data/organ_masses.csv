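# Default reference-adult organ masses (g), overridable per patient.
# Salivary glands follow ICRP 89 (parotid 25 g, submandibular 12.5 g);
# kidneys/liver are adult reference-man values.
region_id,mass_g,model
kidneys,310.0,reference_organ
liver,1800.0,reference_organ
parotid,25.0,sphere
submandibular,12.5,sphere
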