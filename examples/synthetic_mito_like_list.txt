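G00007
G00010
G00017
G00019
G00021
G00030
G00057
G00074
G00087
G00111
G00130
G00161
G00165
G00167
G00177
G00191
G00210
G00215
G00216
G00217
G00263
G00273
G00278
G00293
G00295
G00300
G00304
G00317
G00347
G00354
G00367
G00379
G00401
G00432
G00466
G00483
G00493
G00495
G00498
G00513
G00529
G00530
G00531
G00537
G00539
G00555
G00586
G00596
G00616
G00618
G00623
G00650
G00679
G00683
G00685
G00716
G00739
G00750
G00755
G00775
G00778
G00783
G00796
G00828
G00840
G00841
G00864
G00893
G00909
G00911
G00915
G00921
G00941
G00959
G00986
G00988
G00999
G01010
G01024
G01026
G01027
G01032
G01037
G01038
G01048
G01070
G01093
G01104
G01110
G01139
G01147
G01160
G01187
G01217
G01226
G01232
G01251
G01281
G01328
G01333
G01352
G01360
G01377
G01396
G01400
G01407
G01420
G01439
G01450
G01495
G01507
G01545
G01548
G01554
G01570
G01587
G01596
G01630
G01634
G01637
G01644
G01648
G01666
G01672
G01692
G01719
G01723
G01724
G01735
G01740
G01741
G01749
G01775
G01787
G01799
G01820
G01823
G01856
G01865
G01872
G01876
G01892
G01914
G01932
G01942
G01949
G01956
G01967
G01974
G01995
MT_ABSENT1
MT_ABSENT2
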