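bin_ppm,icc
3.35,0.645
2.51,0.626
8.83,0.625
1.71,0.624
7.29,0.622
1.19,0.621
1.89,0.617
9.11,0.615
6.91,0.613
6.97,0.609
2.33,0.604
1.25,0.594
1.73,0.594
7.61,0.593
7.81,0.593
3.55,0.591
3.41,0.591
7.63,0.590
2.85,0.588
2.65,0.587
7.27,0.586
7.83,0.585
2.17,0.584
7.53,0.583
7.55,0.578
1.47,0.578
2.29,0.578
3.01,0.566
3.15,0.566
3.03,0.565
2.61,0.565
1.17,0.565
2.27,0.550
1.31,0.563
2.43,0.562
1.97,0.562
3.99,0.560
7.35,0.555
6.89,0.552
7.39,0.551
7.41,0.548
2.67,0.547
0.97,0.546
1.93,0.545
3.13,0.544
8.77,0.543
8.53,0.541
3.95,0.540
2.59,0.539
6.85,0.538
0.99,0.537
0.95,0.537
3.93,0.536
3.19,0.535
2.07,0.534
2.53,0.533
2.41,0.532
2.05,0.530
2.03,0.530
1.09,0.529
0.83,0.529
2.25,0.528
2.35,0.526
6.83,0.526
2.31,0.525
0.89,0.524
1.27,0.523
1.01,0.523
2.91,0.522
7.33,0.518
7.43,0.517
7.37,0.517
1.35,0.516
1.87,0.516
7.65,0.515
2.69,0.515
3.45,0.514
3.05,0.513
2.13,0.510
1.77,0.510
3.83,0.510
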