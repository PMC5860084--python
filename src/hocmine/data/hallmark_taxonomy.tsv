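code	name	parent
1	Sustaining proliferative signalling
1.1	Cell cycle	1
1.2	Growth factors growth promoting signals	1
1.2.1	Downstream signalling	1.2
1.3	Receptors	1
2	Evading growth suppressors
2.1	By deregulating cell cycle checkpoints	2
2.1.1	Cell cycle	2.1
2.2	By evading contact inhibition	2
3	Resisting cell death
3.1	Apoptosis	3
3.2	Autophagy	3
3.3	Necrosis	3
4	Enabling replicative immortality
4.1	Immortalization	4
4.2	Senescence	4
5	Inducing angiogenesis
5.1	By deregulating angiogenesis	5
5.1.1	Angiogenic factors	5.1
6	Activating invasion and metastasis
6.1	Invasion	6
6.2	Metastasis	6
7	Genomic instability and mutation
7.1	DNA damage	7
7.1.1	Adducts	7.1
7.1.2	Strand breaks	7.1
7.2	DNA repair mechanisms	7
7.3	Mutation	7
8	Tumor promoting inflammation
8.1	Immune response	8
8.2	Inflammation	8
8.2.2	Oxidative stress	8.2
9	Cellular energetics
9.1	Glycolysis/Warburg effect	9
10	Avoiding immune destruction
10.1	Immune response	10
10.2	Immunosuppression	10
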