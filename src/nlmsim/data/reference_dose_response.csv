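analyte,concentration_mol_dm3,method,aggregate_pct,reported_pm_pct,n_counted
BBSA,1e-13,nlm,9.9,6.3,100
BBSA,1e-11,nlm,26.7,14.0,100
BBSA,1e-9,nlm,67.4,13.4,100
BBSA,1e-7,nlm,18.3,6.9,100
dsDNA,1e-13,nlm,23.4,9.3,100
dsDNA,1e-11,nlm,17.0,9.2,100
dsDNA,1e-9,nlm,53.4,18.4,100
dsDNA,1e-7,nlm,52.0,13.4,100
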