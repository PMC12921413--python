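pathway_id	name	metabolite
map00750	Vitamin B6 metabolism	4-Pyridoxic acid
map00750	Vitamin B6 metabolism	Pyridoxal
map00750	Vitamin B6 metabolism	Pyridoxamine
map00750	Vitamin B6 metabolism	Pyridoxine
map00750	Vitamin B6 metabolism	Pyridoxal 5'-phosphate
map00750	Vitamin B6 metabolism	Gamma-Aminobutyric acid
map00650	Butanoate metabolism	Gamma-Aminobutyric acid
map00650	Butanoate metabolism	Butyric acid
map00650	Butanoate metabolism	Succinic acid
map00650	Butanoate metabolism	Acetoacetic acid
map00650	Butanoate metabolism	3-Hydroxybutyric acid
map00250	Alanine, aspartate and glutamate metabolism	Gamma-Aminobutyric acid
map00250	Alanine, aspartate and glutamate metabolism	L-Glutamic acid
map00250	Alanine, aspartate and glutamate metabolism	L-Glutamine
map00250	Alanine, aspartate and glutamate metabolism	L-Aspartic acid
map00250	Alanine, aspartate and glutamate metabolism	L-Alanine
map00250	Alanine, aspartate and glutamate metabolism	L-Asparagine
map00250	Alanine, aspartate and glutamate metabolism	Fumaric acid
map00260	Glycine, serine and threonine metabolism	Betaine
map00260	Glycine, serine and threonine metabolism	Choline
map00260	Glycine, serine and threonine metabolism	Glycine
map00260	Glycine, serine and threonine metabolism	L-Serine
map00260	Glycine, serine and threonine metabolism	L-Threonine
map00260	Glycine, serine and threonine metabolism	Creatine
map00260	Glycine, serine and threonine metabolism	Sarcosine
map00010	Glycolysis / Gluconeogenesis	Fructose 6-phosphate
map00010	Glycolysis / Gluconeogenesis	Glucose 6-phosphate
map00010	Glycolysis / Gluconeogenesis	Pyruvic acid
map00010	Glycolysis / Gluconeogenesis	Lactic acid
map00010	Glycolysis / Gluconeogenesis	Phosphoenolpyruvic acid
map00500	Starch and sucrose metabolism	Glucose 6-phosphate
map00500	Starch and sucrose metabolism	D-Glucose
map00500	Starch and sucrose metabolism	Sucrose
map00500	Starch and sucrose metabolism	Maltose
map00500	Starch and sucrose metabolism	Trehalose
map00340	Histidine metabolism	3-Methylhistamine
map00340	Histidine metabolism	Histamine
map00340	Histidine metabolism	L-Histidine
map00340	Histidine metabolism	Urocanic acid
map00340	Histidine metabolism	Imidazoleacetic acid
map00270	Cysteine and methionine metabolism	Methylcysteine
map00270	Cysteine and methionine metabolism	L-Cysteine
map00270	Cysteine and methionine metabolism	L-Methionine
map00270	Cysteine and methionine metabolism	S-Adenosylmethionine
map00270	Cysteine and methionine metabolism	Homocysteine
map00270	Cysteine and methionine metabolism	Cystathionine
map04977	Carnitine shuttle / fatty acid oxidation	Propionylcarnitine
map04977	Carnitine shuttle / fatty acid oxidation	L-Carnitine
map04977	Carnitine shuttle / fatty acid oxidation	Acetylcarnitine
map04977	Carnitine shuttle / fatty acid oxidation	Suberylcarnitine
map04977	Carnitine shuttle / fatty acid oxidation	Palmitoylcarnitine
map99001	Gut microbial co-metabolism	Trimethylamine-N-oxide
map99001	Gut microbial co-metabolism	Trimethylamine
map99001	Gut microbial co-metabolism	Indole-3-propionic acid
map99001	Gut microbial co-metabolism	Hippuric acid
map99001	Gut microbial co-metabolism	p-Cresol sulfate
map00230	Purine metabolism	Hypoxanthine
map00230	Purine metabolism	Xanthine
map00230	Purine metabolism	Uric acid
map00230	Purine metabolism	Inosine
map00230	Purine metabolism	Adenosine
map00230	Purine metabolism	Guanosine
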