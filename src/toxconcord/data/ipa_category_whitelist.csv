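category
Hepatocellular carcinoma
Liver Hyperplasia/Hyperproliferation
Liver Cholestasis
Liver Inflammation/Hepatitis
Liver Steatosis
Liver Necrosis/Cell Death
Liver Proliferation
Liver Damage
Liver Fibrosis
Liver Cirrhosis
Liver Failure
Liver Regeneration
Liver Hepatitis
Glomerular Injury
Renal Inflammation
Renal Nephritis
Renal Damage
Renal Tubule Injury
Renal Necrosis/Cell Death
Renal Proliferation
Renal Fibrosis
Renal Failure
Renal Hypertrophy
Kidney Failure
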