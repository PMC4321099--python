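mirna	accession	gene	definition
miR-15a	NM_181412	Zbed4	Mus musculus zinc finger, BED domain containing 4
miR-15a	NM_199302	Lrsam1	Mus musculus leucine-rich repeat and sterile alpha motif containing 1
miR-15a	NM_153522	Scn3b	Mus musculus sodium channel, voltage-gated, type III, beta
miR-15a	NM_178378	Iqcg	Mus musculus IQ motif containing G
miR-15a	NM_008011	Fgfr4	Mus musculus fibroblast growth factor receptor 4
miR-744	NM_181412	Zbed4	Mus musculus zinc finger, BED domain containing 4
miR-744	NM_199302	Lrsam1	Mus musculus leucine-rich repeat and sterile alpha motif containing 1
miR-744	NM_019553	Ddx21	Mus musculus DEAD (Asp-Glu-Ala-Asp) box polypeptide 21
miR-744	NM_001024602	AW555464	Mus musculus expressed sequence AW555464
miR-1196	NM_181412	Zbed4	Mus musculus zinc finger, BED domain containing 4
miR-1196	NM_177312	6330408A02Rik	Mus musculus RIKEN cDNA 6330408A02 gene
miR-1196	NM_134052	Adi1	Mus musculus acireductone dioxygenase 1
miR-1196	NM_001012450	Ankrd6	Mus musculus ankyrin repeat domain 6
miR-1196	NM_019553	Ddx21	Mus musculus DEAD (Asp-Glu-Ala-Asp) box polypeptide 21
miR-1196	NM_010164	Eya1	Mus musculus eyes absent 1 homolog (*Drosophila*)
miR-1196	NM_010517	Igfbp4	Mus musculus insulin-like growth factor binding protein 4
miR-1196	NM_001038609	Mapt	Mus musculus microtubule-associated protein tau
miR-1196	NM_008306	Ndst1	Mus musculus N-deacetylase/N-sulfotransferase (heparan glucosaminyl) 1
miR-1196	NM_001025613	Otud7b	Mus musculus OTU domain containing 7B
miR-1196	NM_145457	Paip1	Mus musculus polyadenylate binding protein-interacting protein 1
miR-1196	NM_183028	Pcmtd1	Mus musculus protein-L-isoaspartate (D-aspartate) O-methyltransferase domain containing 1
miR-1196	NM_018884	Pdzrn3	Mus musculus PDZ domain containing RING finger 3
miR-1196	NM_139269	Pla2g16	Mus musculus phospholipase A2, group XVI
miR-1196	NM_026164	Pnpla8	Mus musculus patatin-like phospholipase domain containing 8
miR-1196	NM_133485	Ppp1r14c	Mus musculus protein phosphatase 1, regulatory (inhibitor) subunit 14c
miR-1196	NM_001081347	Rhobtb1	Mus musculus Rho-related BTB domain containing 1
miR-1196	NM_177766	Slc35e1	Mus musculus solute carrier family 35, member E1
miR-1196	NM_175132	Synpo2l	Mus musculus synaptopodin 2-like
miR-1196	NM_027992	Tmem106b	Mus musculus transmembrane protein 106B
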