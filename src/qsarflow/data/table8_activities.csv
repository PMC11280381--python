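id,pIC50
C01,5.879
C02,6.106
C03,6.827
C04,6.578
C05,6.082
C06,7.125
C07,7.260
C08,7.018
C09,5.770
C10,5.979
C11,6.654
C12,6.449
C13,5.785
C14,7.066
C15,6.842
C16,6.924
C17,5.863
C18,6.629
C19,5.457
C20,7.009
C21,5.487
C22,6.684
C23,6.790
C24,5.678
C25,5.553
C26,5.319
C27,5.585
C28,5.357
C29,6.046
C30,6.357
C31,6.000
C32,5.824
C33,5.886
C34,5.538
C35,5.886
C36,5.658
C37,5.770
C38,5.658
C39,5.620
C40,5.398
C41,5.638
C42,5.387
C43,5.432
C44,6.143
C45,6.959
C46,6.230
C47,6.071
C48,6.208
C49,5.921
C50,6.149
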