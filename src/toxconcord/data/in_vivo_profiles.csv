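substance,organ,effect
Cyproconazole,liver,Cholestasis
Cyproconazole,liver,Hypertrophy
Cyproconazole,liver,Hepatocellular fatty changes
Cyproconazole,liver,Hepatocellular cell degeneration/death
Cyproconazole,liver,Inflammation in the liver
Cyproconazole,liver,Phase I enzyme induction
Fluxapyroxad,liver,Hypertrophy
Fluxapyroxad,liver,Hepatocellular cell degeneration/death
Fluxapyroxad,liver,Neoplasms
Fluxapyroxad,liver,Lesions of biliary epithelium
Fluxapyroxad,liver,Phase I enzyme induction
Azoxystrobin,liver,Hypertrophy
Azoxystrobin,liver,Hepatocellular cell degeneration/death
Azoxystrobin,liver,Inflammation in the liver
Azoxystrobin,liver,Lesions of biliary epithelium
Chlorotoluron,liver,Hepatocellular fatty changes
Chlorotoluron,liver,Inflammation in the liver
Chlorotoluron,kidney,Tubular neoplasms
Thiabendazole,liver,Hypertrophy
Thiabendazole,liver,Lesions of biliary epithelium
Thiabendazole,liver,Phase I enzyme induction
Thiabendazole,kidney,Calculi
Thiabendazole,kidney,Inflammation
Thiabendazole,kidney,Papillary cell degeneration/death
Thiabendazole,kidney,Papillary hypertrophy/hyperplasia
Thiabendazole,kidney,Tubular cell degeneration/death
Thiabendazole,kidney,Tubular fatty changes
Thiabendazole,kidney,Tubular hypertrophy/hyperplasia
2-Phenylphenol,liver,Foci of cellular alteration in the liver
2-Phenylphenol,liver,Neoplasms
2-Phenylphenol,liver,Phase I enzyme induction
2-Phenylphenol,liver,Oxidative stress
2-Phenylphenol,kidney,Calculi
2-Phenylphenol,kidney,Inflammation
2-Phenylphenol,kidney,Oxidative stress
2-Phenylphenol,kidney,Papillary cell degeneration/death
2-Phenylphenol,kidney,Papillary hypertrophy/hyperplasia
2-Phenylphenol,kidney,Pelvis hyperplasia
2-Phenylphenol,kidney,Tubular cell degeneration/death
2-Phenylphenol,kidney,Tubular hypertrophy/hyperplasia
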