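ec	name
2.6.1.42	branched-chain-amino-acid transaminase (BCAT)
4.3.2.1	argininosuccinate lyase (ASL)
3.1.3.1	alkaline phosphatase
1.14.16.1	phenylalanine 4-monooxygenase
4.2.1.22	cystathionine beta-synthase
4.4.1.1	cystathionine gamma-lyase
3.1.3.3	phosphoserine phosphatase
1.3.1.2	dihydropyrimidine dehydrogenase (beta-alanine route)
3.5.2.2	dihydropyrimidinase (beta-alanine route)
3.5.1.6	beta-ureidopropionase (beta-alanine route)
2.6.1.1	aspartate transaminase
2.6.1.2	alanine transaminase
6.3.1.2	glutamine synthetase
6.3.5.4	asparagine synthase
2.1.2.1	serine hydroxymethyltransferase
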