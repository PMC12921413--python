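3-Hydroxybutyric acid
3-Methylhistamine
4-Pyridoxic acid
Acetoacetic acid
Acetylcarnitine
Adenosine
Betaine
Butyric acid
Choline
Creatine
Cystathionine
D-Glucose
Fructose 6-phosphate
Fumaric acid
Gamma-Aminobutyric acid
Glucose 6-phosphate
Glycine
Guanosine
Hippuric acid
Histamine
Homocysteine
Hypoxanthine
Imidazoleacetic acid
Indole-3-propionic acid
Inosine
L-Alanine
L-Asparagine
L-Aspartic acid
L-Carnitine
L-Cysteine
L-Glutamic acid
L-Glutamine
L-Histidine
L-Methionine
L-Serine
L-Threonine
Lactic acid
Maltose
Methylcysteine
Palmitoylcarnitine
Phosphoenolpyruvic acid
Propionylcarnitine
Pyridoxal
Pyridoxal 5'-phosphate
Pyridoxamine
Pyridoxine
Pyruvic acid
S-Adenosylmethionine
Sarcosine
Suberylcarnitine
Succinic acid
Sucrose
Trehalose
Trimethylamine
Trimethylamine-N-oxide
Uric acid
Urocanic acid
Xanthine
p-Cresol sulfate
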