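income_tax
5.9
20.4
14.9
16.2
17.2
7.8
6.1
9.2
10.2
9.6
13.3
8.5
21.6
18.5
5.1
6.7
17.0
8.6
9.7
39.2
35.7
15.7
9.7
10.0
4.1
36.0
8.5
8.0
9.2
26.2
21.9
16.7
21.3
35.4
14.3
8.5
10.6
19.1
20.5
7.1
7.7
18.1
16.5
11.9
7.0
8.6
12.5
10.3
11.2
6.1
8.4
11.0
11.6
11.9
5.2
6.8
8.9
7.1
10.8
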