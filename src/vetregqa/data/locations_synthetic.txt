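# Synthetic hatchery location list (five-digit aquaculture site numbers).
# Stand-in for the national register of juvenile-salmonid sites, which is
# not redistributable; the synthetic generator draws owner locations from it.
10310
10915
11509
11682
12731
12818
12969
14125
14452
14801
15777
15803
16739
17165
17369
17665
19125
19208
19234
19877
20642
21482
21769
21970
22597
22784
23636
24295
25046
25289
25291
25583
26570
26741
28801
29177
29595
29825
30692
31233
32203
32514
32609
33593
33815
34098
36331
36994
37080
37115
37309
37377
39164
39192
40006
41431
41803
44110
45459
45858
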