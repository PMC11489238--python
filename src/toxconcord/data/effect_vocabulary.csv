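organ,effect
liver,Cholestasis
liver,Hypertrophy
liver,Hepatocellular fatty changes
liver,Hepatocellular cell degeneration/death
liver,Inflammation in the liver
liver,Phase I enzyme induction
liver,Neoplasms
liver,Lesions of biliary epithelium
liver,Foci of cellular alteration in the liver
liver,Oxidative stress
kidney,Tubular neoplasms
kidney,Tubular hypertrophy/hyperplasia
kidney,Tubular cell degeneration/death
kidney,Tubular fatty changes
kidney,Papillary cell degeneration/death
kidney,Papillary hypertrophy/hyperplasia
kidney,Pelvis hyperplasia
kidney,Calculi
kidney,Inflammation
kidney,Oxidative stress
kidney,Glomerular cell degeneration
kidney,Glomerular inflammation
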