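Number,Sex,Side,Age at diagnosis (years),Age at intervention (years),Herring classification,Follow-up time (months)
1,Male,Left,6.3,6.6,C,10
2,Male,Left,6.5,7.5,B,8
3,Female,Left,6.0,8.2,B,6
4,Male,Left,5.5,6.3,B,7
5,Male,Left,8.5,9.0,B,17
6,Male,Left,7.2,8.6,C,12
7,Female,Left,5.0,5.3,B,12
8,Male,Right,5.5,6.0,C,7
9,Male,Right,5.5,6.0,C,7
10,Male,Right,4.6,5.5,C,7
11,Male,Left,4.5,5.5,C,7
12,Male,Right,5.0,5.3,C,8
13,Male,Left,7.5,8.2,C,13
14,Male,Right,4.0,7.0,C,10
15,Male,Left,3.5,4.5,C,8
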