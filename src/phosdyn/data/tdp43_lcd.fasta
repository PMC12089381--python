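>tdp43_lcd offset=261 | TDP-43 low-complexity domain, UniProt Q13148 residues 261-414
EPKHNSNRQLERSGRFGGNPGGFGNQGGFGNSRGGGAGLGNNQGSNMGGGMNFGAFSINP
AMMAAAQAALQSSWGMMGMLASQQNQSGPSGNNQNQGNMQREPNQAFGSGNNSYSGSNSG
AAIGWGSASNAGSGSGFNGGFGSSMDSKSSGWGM
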