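fpg,cpeptide,homa2b,homa2ir
3.0,0.2,181.82,0.2182
3.0,0.4,363.64,0.4364
3.0,0.55,500.0,0.6
3.0,0.8,727.27,0.8727
3.0,1.2,1090.91,1.3091
3.0,2.0,1818.18,2.1818
3.0,3.5,3181.82,3.8182
4.0,0.2,60.61,0.2909
4.0,0.4,121.21,0.5818
4.0,0.55,166.67,0.8
4.0,0.8,242.42,1.1636
4.0,1.2,363.64,1.7455
4.0,2.0,606.06,2.9091
4.0,3.5,1060.61,5.0909
5.0,0.2,36.36,0.3636
5.0,0.4,72.73,0.7273
5.0,0.55,100.0,1.0
5.0,0.8,145.45,1.4545
5.0,1.2,218.18,2.1818
5.0,2.0,363.64,3.6364
5.0,3.5,636.36,6.3636
6.5,0.2,22.73,0.4727
6.5,0.4,45.45,0.9455
6.5,0.55,62.5,1.3
6.5,0.8,90.91,1.8909
6.5,1.2,136.36,2.8364
6.5,2.0,227.27,4.7273
6.5,3.5,397.73,8.2727
8.0,0.2,16.53,0.5818
8.0,0.4,33.06,1.1636
8.0,0.55,45.45,1.6
8.0,0.8,66.12,2.3273
8.0,1.2,99.17,3.4909
8.0,2.0,165.29,5.8182
8.0,3.5,289.26,10.1818
10.0,0.2,12.12,0.7273
10.0,0.4,24.24,1.4545
10.0,0.55,33.33,2.0
10.0,0.8,48.48,2.9091
10.0,1.2,72.73,4.3636
10.0,2.0,121.21,7.2727
10.0,3.5,212.12,12.7273
14.0,0.2,7.91,1.0182
14.0,0.4,15.81,2.0364
14.0,0.55,21.74,2.8
14.0,0.8,31.62,4.0727
14.0,1.2,47.43,6.1091
14.0,2.0,79.05,10.1818
14.0,3.5,138.34,17.8182
18.0,0.2,5.87,1.3091
18.0,0.4,11.73,2.6182
18.0,0.55,16.13,3.6
18.0,0.8,23.46,5.2364
18.0,1.2,35.19,7.8545
18.0,2.0,58.65,13.0909
18.0,3.5,102.64,22.9091
25.0,0.2,4.04,1.8182
25.0,0.4,8.08,3.6364
25.0,0.55,11.11,5.0
25.0,0.8,16.16,7.2727
25.0,1.2,24.24,10.9091
25.0,2.0,40.4,18.1818
25.0,3.5,70.71,31.8182
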