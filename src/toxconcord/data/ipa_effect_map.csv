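categories,organ,effect
Hepatocellular carcinoma|Liver Hyperplasia/Hyperproliferation,liver,Neoplasms
Liver Cholestasis,liver,Cholestasis
Liver Cholestasis|Liver Inflammation/Hepatitis,liver,Cholestasis
Liver Cholestasis|Liver Inflammation/Hepatitis,liver,Inflammation in the liver
Liver Hyperplasia/Hyperproliferation,liver,Neoplasms
Liver Inflammation/Hepatitis,liver,Inflammation in the liver
Liver Inflammation/Hepatitis|Liver Steatosis,liver,Hepatocellular fatty changes
Liver Inflammation/Hepatitis|Liver Steatosis,liver,Inflammation in the liver
Liver Necrosis/Cell Death,liver,Hepatocellular cell degeneration/death
Liver Proliferation,liver,Foci of cellular alteration in the liver
Liver Proliferation,liver,Neoplasms
Liver Steatosis,liver,Hepatocellular fatty changes
Glomerular Injury,kidney,Glomerular cell degeneration
Glomerular Injury|Renal Inflammation|Renal Nephritis,kidney,Glomerular cell degeneration
Glomerular Injury|Renal Inflammation|Renal Nephritis,kidney,Glomerular inflammation
Glomerular Injury|Renal Inflammation|Renal Nephritis,kidney,Inflammation
Renal Damage|Renal Tubule Injury,kidney,Tubular cell degeneration/death
Renal Inflammation|Renal Nephritis,kidney,Inflammation
Renal Necrosis/Cell Death,kidney,Tubular cell degeneration/death
Renal Necrosis/Cell Death,kidney,Glomerular cell degeneration
Renal Necrosis/Cell Death,kidney,Papillary cell degeneration/death
Renal Proliferation,kidney,Tubular neoplasms
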