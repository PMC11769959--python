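metabolite,class
alanine,amino acids
arginine,amino acids
asparagine,amino acids
aspartate,amino acids
cysteine,amino acids
glutamate,amino acids
glutamine,amino acids
glycine,amino acids
histidine,amino acids
isoleucine,amino acids
leucine,amino acids
lysine,amino acids
methionine,amino acids
ornithine,amino acids
phenylalanine,amino acids
proline,amino acids
serine,amino acids
taurine,amino acids
threonine,amino acids
tryptophan,amino acids
tyrosine,amino acids
valine,amino acids
ATP,bioenergetics
ADP,bioenergetics
AMP,bioenergetics
NAD+,bioenergetics
NADH,bioenergetics
NADP+,bioenergetics
creatine,bioenergetics
phosphocreatine,bioenergetics
lactate,bioenergetics
pyruvate,bioenergetics
succinate,bioenergetics
fumarate,bioenergetics
malate,bioenergetics
citrate,bioenergetics
2-phosphoglycerate,bioenergetics
acetate,bioenergetics
glutathione,peptides
oxidized glutathione,peptides
carnosine,peptides
anserine,peptides
homocarnosine,peptides
glycylglycine,peptides
glycylproline,peptides
alanylglutamine,peptides
gamma-glutamylcysteine,peptides
cysteinylglycine,peptides
alanylalanine,peptides
leucylglycine,peptides
seryltyrosine,peptides
valylleucine,peptides
glutamylglutamate,peptides
prolylglycine,peptides
glucose,carbohydrates
glucose-6-phosphate,carbohydrates
fructose,carbohydrates
galactose,carbohydrates
mannose,carbohydrates
ribose,carbohydrates
maltose,carbohydrates
sucrose,carbohydrates
glycogen,carbohydrates
UDP-glucose,carbohydrates
sn-glycero-3-phosphocholine,lipids
choline,lipids
phosphocholine,lipids
ethanolamine,lipids
phosphoethanolamine,lipids
glycerol,lipids
myo-inositol,lipids
carnitine,lipids
formate,organic acids
2-hydroxybutyrate,organic acids
3-hydroxybutyrate,organic acids
2-oxoglutarate,organic acids
isocitrate,organic acids
methylmalonate,organic acids
ascorbate,organic acids
putrescine,amines
spermidine,amines
trimethylamine,amines
trimethylamine N-oxide,amines
dimethylamine,amines
adenosine,nucleosides
inosine,nucleosides
uridine,nucleosides
cytidine,nucleosides
unknown U1,unknown
unknown U2,unknown
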