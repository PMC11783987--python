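group,start_len,end_len,count
Closed ISR,0,0,232
Closed ISR,0,1,83
Closed ISR,0,2,39
Closed ISR,0,3,20
Closed ISR,0,4,31
Closed ISR,0,5,25
Closed ISR,1,0,392
Closed ISR,1,1,135
Closed ISR,1,2,74
Closed ISR,1,3,52
Closed ISR,1,4,31
Closed ISR,1,5,0
Closed ISR,2,0,412
Closed ISR,2,1,171
Closed ISR,2,2,97
Closed ISR,2,3,58
Closed ISR,2,4,2
Closed ISR,3,0,448
Closed ISR,3,1,211
Closed ISR,3,2,93
Closed ISR,3,3,0
Closed ISR,4,0,588
Closed ISR,4,1,244
Closed ISR,4,2,5
Closed ISR,5,0,331
Closed ISR,5,1,7
Closed ISR,6,0,2347
Open ISR,0,0,377
Open ISR,0,1,86
Open ISR,0,2,50
Open ISR,0,3,31
Open ISR,0,4,30
Open ISR,0,5,30
Open ISR,1,0,569
Open ISR,1,1,171
Open ISR,1,2,60
Open ISR,1,3,32
Open ISR,1,4,60
Open ISR,1,5,0
Open ISR,2,0,654
Open ISR,2,1,209
Open ISR,2,2,95
Open ISR,2,3,69
Open ISR,2,4,0
Open ISR,3,0,595
Open ISR,3,1,190
Open ISR,3,2,163
Open ISR,3,3,1
Open ISR,4,0,733
Open ISR,4,1,405
Open ISR,4,2,5
Open ISR,5,0,626
Open ISR,5,1,0
Open ISR,5,2,2
Open ISR,6,0,943
Blanks,0,0,367
Blanks,0,1,84
Blanks,0,2,34
Blanks,0,3,17
Blanks,0,4,19
Blanks,0,5,38
Blanks,1,0,542
Blanks,1,1,112
Blanks,1,2,40
Blanks,1,3,26
Blanks,1,4,51
Blanks,1,5,1
Blanks,2,0,612
Blanks,2,1,159
Blanks,2,2,65
Blanks,2,3,75
Blanks,2,4,0
Blanks,2,5,1
Blanks,3,0,529
Blanks,3,1,179
Blanks,3,2,139
Blanks,3,3,1
Blanks,3,4,1
Blanks,4,0,793
Blanks,4,1,427
Blanks,4,2,1
Blanks,5,0,589
Blanks,5,1,2
Blanks,6,0,1294
Open RoO,0,0,197
Open RoO,0,1,63
Open RoO,0,2,26
Open RoO,0,3,23
Open RoO,0,4,19
Open RoO,0,5,31
Open RoO,1,0,286
Open RoO,1,1,134
Open RoO,1,2,79
Open RoO,1,3,74
Open RoO,1,4,50
Open RoO,1,5,0
Open RoO,2,0,349
Open RoO,2,1,196
Open RoO,2,2,111
Open RoO,2,3,34
Open RoO,2,4,0
Open RoO,3,0,321
Open RoO,3,1,270
Open RoO,3,2,49
Open RoO,3,3,1
Open RoO,3,4,3
Open RoO,4,0,485
Open RoO,4,1,117
Open RoO,4,2,4
Open RoO,5,0,127
Open RoO,5,1,8
Open RoO,5,2,1
Open RoO,6,0,2739
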