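>ck1d_synthetic offset=1 | SYNTHETIC stand-in for CK1d (UniProt P48730, 415 aa): random kinase-like composition with the Asp149-Phe150-Gly151 active-site triad; supply the real P48730 FASTA for production use
AGPYRCTMLLDTNNTSFAVIKEAGCFEKFKYDKVRLQDMKVLCPRGNQLDKLMMKPLDYS
YLYTVQVPADRSVLRGLPSKRKYISMLLGFPTMLSNNGAHKHIGPTVSSTYVLRLRDLIY
TFAILPWAASDFQMIANQLISEGGAAVEDFGDRETTFAIGAKNEGNVGALSATLSTDRAL
DELGTGDYKKELLKNKSMILFLQGIPFYGDNRMGAFIVGCMATLPLVLILLLGSKAHNEA
PYKAAPLADPAANEIKEGGREANFRDSHDDLERILPEPKQANNMAENNMDAAESGLELAE
VLRDQTIASWNVQHFWMSKSALEYFSYRTTSYPLQYANLSQRGIKEPRIGGYAYQWTAHS
SFETILGTGQGLPSQVLKDKRFKPPRAKTTNPVTSEAAAWPAGDGIMKLFELGCK
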