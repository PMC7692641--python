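>A9K
AAAAAAAAAK
>hCAP-18
FRKSKEKIGKEFKRIVQRIKDFLRNLVPRTES
>HPRP-A1-TAT
FKKLKKLFSKLWNWKRKKRRQRRR
>KLA
KLAKLAKKLAKLAK
>Lactoferricin-B
FKCRRWQWRMKKLGAPSITCVRRAF
>Magainin-1
GIGKFLHSAGKFGKAFVGEIMKS
>Mastoparan-C
LNLKALLAVAKKIL
>NGR-peptide-1
CNGRCGGKLAKLAKKLAKLAK
>GW-H1
GYNYAKKLANLAKKFANALW
>Pleurocidin-NRC-03
GRRKRKWLRRIGKGVKIIGGAALDHL
>R7-kla
RRRRRRRKLAKLAKKLAKLAK
>RGD-4C-GG-KLAKLAK2
ACDCRGDCFCGGKLAKLAKKLAKLAK
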