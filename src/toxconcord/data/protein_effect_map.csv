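cellular_function,organ,effect
Translation,liver,Neoplasms
Translation,liver,Foci of cellular alteration in the liver
Translation,liver,Hypertrophy
Translation,kidney,Tubular neoplasms
Translation,kidney,Tubular hypertrophy/hyperplasia
Cell division,liver,Neoplasms
Cell division,liver,Foci of cellular alteration in the liver
Cell division,kidney,Tubular neoplasms
Cell division,kidney,Tubular hypertrophy/hyperplasia
Oxidative/heat stress,liver,Oxidative stress
Oxidative/heat stress,kidney,Oxidative stress
Autophagy,liver,Hepatocellular cell degeneration/death
Autophagy,kidney,Tubular cell degeneration/death
Apoptosis,liver,Hepatocellular cell degeneration/death
Apoptosis,kidney,Tubular cell degeneration/death
Transcription,liver,Neoplasms
Transcription,liver,Foci of cellular alteration in the liver
Transcription,liver,Hypertrophy
Transcription,kidney,Tubular neoplasms
Transcription,kidney,Tubular hypertrophy/hyperplasia
Protein degradation,liver,
Protein degradation,kidney,
Hypoxia,liver,
Hypoxia,kidney,
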