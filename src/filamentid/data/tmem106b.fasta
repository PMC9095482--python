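>sp|Q9NUM4|T106B_HUMAN Transmembrane protein 106B, Homo sapiens; ordered filament core S120-G254; N-glycosylation at N145,N151,N164,N183,N256; disulfide C214-C253
MGKSLSHLPLHSSKEDAYDGVTSENMRNGLVNSEVHNEDGRNGDVSQFPYVEFTGRDSVT
CPTCQGTGRIPRGQENQLVALIPYSDQRLRPRRTKLYVMASVFVCLLLSGLAVFFLFPRS
IDVKYIGVKSAYVSYDVQKRTIYLNITNTLNITNNNYYSVEVENITAQVQFSKTVIGKAR
LNNITIIGPLDMKQIDYTVPTVIAEEMSYMYDFCTLISIKVHNIVLMMQVTVTTTYFGHS
EQISQERYQYVDCGRNTTYQLGQSEYLNVLQPQQ
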