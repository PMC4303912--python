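name,mw_g_per_mol,pka,pka_kind,log_kow,specific_activity_ci_per_mmol,log_kow_ph_adjusted,environmental_ng_per_L
propranolol,259.34,9.42,base,2.54,29.0,1.12,33
metoprolol,267.364,9.6,base,1.76,29.7,-0.90,410
atenolol,266.336,9.6,base,0.67,7.3,0.0015,940
formoterol,344.405,7.9;9.2,acid;base,1.93,18.5,0.41,
terbutaline,225.284,8.86;9.76,acid;base,1.25,29.0,,1297
ranitidine,314.4,8.08,base,1.47,2.5,,120
imipramine,280.407,9.4,base,4.39,48.5,0.14,
mannitol,182.172,13.5,acid,-3.1,20.0,,
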