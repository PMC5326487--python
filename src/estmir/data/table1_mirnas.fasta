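>ppt-miR414 known mature miRNA (Physcomitrella patens)
UCAUCCUCAUCAUCCUCGUCC
>csa-miR414-predicted predicted mature miRNA (Crocus sativus, contig65)
UCCCUCUCAUCAUCCUCGUCG
>aly-miR837-5p known mature miRNA (Arabidopsis lyrata)
CAUUGUUUCUUGUUUUUUUCA
>csa-miR837-5p-predicted predicted mature miRNA (Crocus sativus, contig441)
CUUUGUUUCUUGUUUUCCUCC
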