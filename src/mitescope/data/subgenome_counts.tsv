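genome	family	subgenome	count
Tturgidum	ALL	A	29844
Tturgidum	ALL	B	46074
Tturgidum	ALL	unknown	2154
Taestivum	ALL	A	31424
Taestivum	ALL	B	47324
Taestivum	ALL	D	33787
Tturgidum	Thalos	A	9689
Tturgidum	Thalos	B	17522
Tturgidum	Thalos	unknown	735
Taestivum	Thalos	A	9699
Taestivum	Thalos	B	17202
Taestivum	Thalos	D	14600
Tturgidum	Minos	A	827
Tturgidum	Minos	B	167
Tturgidum	Minos	unknown	28
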