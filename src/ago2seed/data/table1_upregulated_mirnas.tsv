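timepoint	threshold	mirna
isc2h_rep0h	log2>1	miR-215
rep4h	log2>1	miR-493
rep1d	log2>3	miR-466d-5p
rep1d	log2>3	miR-466k
rep1d	log2>3	miR-466b-5p
rep1d	log2>3	miR-468
rep1d	log2>3	miR-466f-5p
rep1d	log2>3	miR-672
rep1d	log2>3	miR-669b
rep1d	log2>3	miR-669e
rep1d	log2>3	miR-466a-5p
rep1d	log2>3	miR-466h
rep1d	log2>3	miR-210
rep1d	log2>3	miR-670
rep1d	log2>3	miR-467c
rep1d	log2>3	miR-466e-5p
rep1d	log2>3	miR-669a
rep1d	log2>2	miR-467e
rep1d	log2>2	miR-466c-5p
rep1d	log2>2	miR-466j
rep1d	log2>2	miR-669d
rep1d	log2>2	miR-125b-3p
rep1d	log2>2	miR-16
rep1d	log2>2	miR-669g
rep1d	log2>2	miR-696
rep1d	log2>2	miR-18b
rep1d	log2>2	miR-297a
rep1d	log2>2	miR-297c
rep1d	log2>2	miR-493
rep1d	log2>2	miR-467h
rep1d	log2>2	miR-297b-5p
rep1d	log2>2	miR-15a
rep1d	log2>2	miR-669c
rep1d	log2>2	miR-467b
rep1d	log2>2	miR-1188
rep1d	log2>2	miR-122
rep1d	log2>2	miR-711
rep1d	log2>2	miR-466f
rep1d	log2>2	miR-214
rep1d	log2>2	miR-99b
rep1d	log2>2	miR-465b-5p
rep1d	log2>2	miR-346
rep1d	log2>2	miR-673-3p
rep1d	log2>2	miR-681
rep1d	log2>2	miR-93
rep1d	log2>2	miR-1906
rep1d	log2>2	miR-1186
rep1d	log2>2	miR-546
rep1d	log2>2	miR-342-5p
rep1d	log2>2	miR-21
rep1d	log2>1	miR-1903
rep1d	log2>1	miR-296-3p
rep1d	log2>1	miR-677
rep1d	log2>1	miR-744
rep1d	log2>1	miR-669h-5p
rep1d	log2>1	miR-106b
rep1d	log2>1	miR-683
rep1d	log2>1	miR-1196
rep1d	log2>1	miR-449b
rep1d	log2>1	miR-1194
rep1d	log2>1	miR-338-5p
rep1d	log2>1	miR-760
rep1d	log2>1	miR-1892
rep1d	log2>1	miR-141
rep1d	log2>1	miR-330
rep1d	log2>1	miR-689
rep1d	log2>1	miR-547
rep1d	log2>1	miR-574-5p
rep1d	log2>1	miR-1187
rep1d	log2>1	miR-298
rep1d	log2>1	miR-98
rep1d	log2>1	miR-449c
rep1d	log2>1	miR-680
rep1d	log2>1	miR-105
rep1d	log2>1	miR-712
rep1d	log2>1	miR-291a-5p
rep1d	log2>1	miR-542-5p
rep1d	log2>1	miR-92a
rep1d	log2>1	miR-292-5p
rep1d	log2>1	miR-764-3p
rep1d	log2>1	miR-30b
rep1d	log2>1	miR-705
rep1d	log2>1	miR-20b
rep1d	log2>1	miR-294
rep1d	log2>1	miR-764-5p
rep1d	log2>1	miR-1907
rep1d	log2>1	miR-881
rep1d	log2>1	miR-1896
rep1d	log2>1	miR-423-5p
rep1d	log2>1	miR-691
rep1d	log2>1	miR-7a
rep1d	log2>1	miR-292-3p
rep1d	log2>1	miR-302c
rep1d	log2>1	miR-1893
rep1d	log2>1	miR-1224
rep1d	log2>1	miR-302d
rep1d	log2>1	miR-214
rep1d	log2>1	miR-28
rep1d	log2>1	miR-710
rep1d	log2>1	miR-291b-5p
rep1d	log2>1	miR-685
rep1d	log2>1	miR-877
rep1d	log2>1	miR-370
rep1d	log2>1	miR-135a
rep1d	log2>1	miR-218
rep1d	log2>1	miR-770-3p
rep1d	log2>1	miR-383
rep1d	log2>1	miR-674
rep1d	log2>1	miR-31
rep1d	log2>1	miR-190b
rep1d	log2>1	miR-433
rep1d	log2>1	miR-671-3p
rep1d	log2>1	miR-682
rep1d	log2>1	miR-450b-5p
rep1d	log2>1	miR-743b-5p
rep1d	log2>1	miR-665
rep1d	log2>1	miR-667
rep1d	log2>1	miR-1898
rep1d	log2>1	miR-488
rep1d	log2>1	miR-511
rep1d	log2>1	miR-679
rep1d	log2>1	miR-453
rep1d	log2>1	miR-678
rep1d	log2>1	miR-615-5p
rep1d	log2>1	miR-1897-5p
rep1d	log2>1	miR-101a
rep1d	log2>1	miR-693-3p
rep1d	log2>1	miR-327
rep1d	log2>1	miR-129-5p
rep7d	log2>2	miR-21
rep7d	log2>2	miR-466d-3p
rep7d	log2>2	miR-467b
rep7d	log2>2	miR-551b
rep7d	log2>2	miR-467e
rep7d	log2>2	miR-466g
rep7d	log2>2	miR-297a
rep7d	log2>2	miR-467g
rep7d	log2>2	miR-467a
rep7d	log2>1	miR-214
rep7d	log2>1	miR-466l
rep7d	log2>1	miR-466f-3p
rep7d	log2>1	miR-669i
rep7d	log2>1	miR-466i
rep7d	log2>1	miR-466a-3p
rep7d	log2>1	miR-31
rep7d	log2>1	miR-669f
rep7d	log2>1	miR-574-3p
rep7d	log2>1	miR-669h-3p
rep7d	log2>1	miR-467f
rep7d	log2>1	miR-215
rep7d	log2>1	miR-466b-3-3p
rep7d	log2>1	miR-142-3p
rep7d	log2>1	miR-207
rep7d	log2>1	miR-1192
rep7d	log2>1	miR-713
rep7d	log2>1	miR-674
rep7d	log2>1	miR-199a-5p
rep7d	log2>1	miR-206
rep7d	log2>1	miR-706
rep7d	log2>1	miR-1-2-as
rep7d	log2>1	miR-1903
rep7d	log2>1	miR-197
rep7d	log2>1	miR-15b
rep7d	log2>1	miR-501-3p
rep7d	log2>1	miR-199a-3p
rep7d	log2>1	miR-464
rep7d	log2>1	miR-698
rep7d	log2>1	miR-582-3p
rep7d	log2>1	miR-488
rep7d	log2>1	miR-1186
rep7d	log2>1	miR-330
rep7d	log2>1	miR-335-3p
rep7d	log2>1	miR-222
rep7d	log2>1	miR-351
rep7d	log2>1	miR-346
rep7d	log2>1	miR-467h
rep7d	log2>1	miR-878-3p
rep7d	log2>1	miR-717
rep7d	log2>1	miR-1196
rep7d	log2>1	miR-685
rep7d	log2>1	miR-671-3p
rep7d	log2>1	miR-542-3p
rep7d	log2>1	miR-669d
rep7d	log2>1	miR-467b
rep7d	log2>1	miR-503
rep7d	log2>1	miR-1894-5p
rep7d	log2>1	miR-877
rep7d	log2>1	miR-667
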