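precursor	peptide	sequence	mh_printed	comment	analyzable
Acyl-CoA binding protein	ODN peptide	TVGDVNTDRPGMLDF	1637.56		Yes
Cerebellin-1 pre.	Cerebellin-1	SGSAKVAFSAIRSTNH	1632.85		Yes
Cerebellin-2 pre.	Cerebellin-2	SGSAKVAFSATRSTNH	1620.80
Cerebellin-4 pre.	Cerebellin-4	ANSKVAFSAVRSTN	1451.70		Yes
Cerebellin-4 pre.	Cerebellin-4	SKVAFSAVRSTN	1267.36		Yes
Gastrin-releasing peptide	GRP	APLQPGGSPALTKIYPR	1766.69		Yes
Gastrin-releasing peptide	GRP	APLQPGGSPALTKIYP	1608.89
Gonadotropin-inhibiting hormone	GnIH propep	SVPISLSQGVQESEPGM	1743.83
Gonadotropin-inhibiting hormone	GnIH-RP2	SPLARSSIQSLLNLPQ	1723.97
Gonadotropin-inhibiting hormone	GnIH-RP2	ARSSIQSLLNLPQ	1426.80	companion table prints ARSSIQSLLNLSQ	Yes
Glucagon family neuropeptides	PACAP27	HIDGIFTDSYSRY	1573.73
Neuropeptide Y (NPY) pre.	NPY	SSPETLISDLLLR	1443.81
Prepronociceptin (PNOC) pre	Precursor	AVASPLQVSELL	1226.82		Yes
Prepronociceptin (PNOC) pre	Nociceptin	YGGFIGVRKSARKWNNQ	1981.07		Yes
Prepronociceptin (PNOC) pre	Nociceptin	YGGFIGVRKSA	1154.63		Yes
Prepronociceptin (PNOC) pre	Nociceptin	YGGFIGVRK	996.56
Prepronociceptin (PNOC) pre	Neuropeptide1	GSWPAARGVQ	1981.05		Yes
Prepronociceptin (PNOC) pre	Neuropeptide2	FSEFLKQYLGMSPR	1702.86		Yes
Prepronociceptin (PNOC) pre	Neuropeptide2	SEFLKQYLGMSPR	1555.79		Yes
Proenkephalin A (PENK) pre	Precursor	MDELYHPESEDEANGGEILA	2218.94
Proenkephalin A (PENK) pre	Precursor	MDELYHPESEDEANGGEIL	2147.91
Proenkephalin A (PENK) pre	Precursor	DELYHPESEDEANGGEILA	2087.90
Proenkephalin A (PENK) pre	Precursor	ELYHPESEDEANGGEILA	1972.44		Yes
Proenkephalin A (PENK) pre	Precursor	ELYHPESEDEANGGEIL	1901.84
Proenkephalin A (PENK) pre	Precursor	LYHPESEDEANGGEILA	1843.83
Proenkephalin A (PENK) pre	Precursor	YHPESEDEANGGEILA	1730.75
Proenkephalin A (PENK) pre	Precursor	YHPESEDEANGGEIL	1659.72
Proenkephalin A (PENK) pre	Precursor	HPESEDEANGGEIL	1496.65
Proenkephalin A (PENK) pre	Precursor	VGRPEWWLDYQ	1448.69		Yes
Proenkephalin A (PENK) pre	Precursor	SPELEDEAKELQ	1387.62		Yes
Proenkephalin A (PENK) pre	Precursor	SPELEDEAKEL	1259.90		Yes
Proenkephalin A (PENK) pre	Precursor	ELEDEAKELQ	1203.57
Proenkephalin A (PENK) pre	Precursor	LEDEAKELQ	1074.99		Yes
Proenkephalin A (PENK) pre	MERF	YGGFMRF	877.40		Yes
Proenkephalin A (PENK) pre	MERSL	YGGFMRSL	930.45		Yes
Proenkephalin B (PENK) pre	Precursor	PKLKWDNQ	1028.80		Yes
Protachykinin 1 (PPT) pre	C-term flanking peptide (CTFP)	SLNSGSSERSIAQNYE	1741.07		Yes
Protachykinin 1 (PPT) pre	C-term flanking peptide (CTFP)	SLNSGSSERSIAQNYE	1821.77	S6/7(p)	Yes
Protachykinin 1 (PPT) pre	C-term flanking peptide (CTFP)	SLNSGSSERSIAQNYE	1900.26	S6/7, S10(p)	Yes
Protachykinin 1 (PPT) pre	Substance P	RPRPQQFFGLM		sequence recovered from companion table; MH+ not printed	Yes
Protachykinin 1 (PPT) pre	Neuropeptide K	DAGYGQISH	947.42		Yes
Protachykinin 1 (PPT) pre	Neuropeptide K	AGYGQISH	832.40
Protachykinin 1 (PPT) pre	Neurokinin A	HKTDSFVGLM	1133.87	M-amide	Yes
Secretogranin-1 pre	Secretogranin1- propep	QYDKMDQLAQLLNY	1725.81	Pyroglutamic Acid
Secretogranin-1 pre	Secretogranin1	IHEGEEGEAEEE	1357.54		Yes
Secretogranin-2 pre	Secretoneurin	TNEIVEEQYTPQSLATLE	2064.99
Secretogranin-2 pre	Secretoneurin	TNEIVEEQYTPQSL	1650.79		Yes
Secretogranin-2 pre	Secretoneurin	TNEIVEEQYTPQS	1537.70
Secretogranin-2 pre	Secretogranin2	SGKLSFLEDEM	1255.59
Secretogranin-2 pre	Secretogranin2	SGKLSFLEDE	1124.55		Yes
Secretogranin-2 pre	Secretogranin2	SGKLSFLE	880.478
Secretogranin-5 pre	C-terminal peptide (CTP)	SVNPYLQGKRLDNVVA	1772.96		Yes
Secretogranin-5 pre	C-terminal peptide (CTP)	SVNPYLQGKRLDNVV	1701.63		Yes
Somatostatin pre	SMS-propep	SLAAAAGKQELAK	1256.71
Somatostatin pre	SMS-14	KNFFWKTFTSC	1409.18		Yes
Somatostatin pre	SMS-14	FWKTFTSC	1019.90		Yes
Somatostatin pre	SMS-28	SANSNPALAPRE	1226.61		Yes
Somatostatin pre	SMS-28	SANSNPALAPR	1097.57
Somatostatin pre	SMS-28	ANSNPALAPRE	1139.58
Vasoactive intestinal peptide	VIP	AVFTDNYSRF	1219.7		Yes
CRMP-2	CRMP-2 peptide	APPGGRANITSLG	1210.81		Yes
FKBP5	FKBP5 peptide	ANAGPNTNGSQFFICTA	1712.77		Yes
Stathmin	Stathmin peptide	ASGQAFELILGPR	1358.74
Thymosin beta	Thymosin beta peptide	SDKPDMAEIEKFDK	1566.84		Yes
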