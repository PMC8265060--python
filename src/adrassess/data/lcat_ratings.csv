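case_id,rater_id,tool,outcome
case_0001,rater1,LCAT,unlikely
case_0001,rater2,LCAT,unlikely
case_0002,rater1,LCAT,unlikely
case_0002,rater2,LCAT,unlikely
case_0003,rater1,LCAT,unlikely
case_0003,rater2,LCAT,unlikely
case_0004,rater1,LCAT,unlikely
case_0004,rater2,LCAT,possible
case_0005,rater1,LCAT,possible
case_0005,rater2,LCAT,possible
case_0006,rater1,LCAT,possible
case_0006,rater2,LCAT,possible
case_0007,rater1,LCAT,possible
case_0007,rater2,LCAT,possible
case_0008,rater1,LCAT,possible
case_0008,rater2,LCAT,possible
case_0009,rater1,LCAT,possible
case_0009,rater2,LCAT,possible
case_0010,rater1,LCAT,possible
case_0010,rater2,LCAT,possible
case_0011,rater1,LCAT,possible
case_0011,rater2,LCAT,possible
case_0012,rater1,LCAT,possible
case_0012,rater2,LCAT,probable
case_0013,rater1,LCAT,possible
case_0013,rater2,LCAT,probable
case_0014,rater1,LCAT,possible
case_0014,rater2,LCAT,probable
case_0015,rater1,LCAT,probable
case_0015,rater2,LCAT,probable
case_0016,rater1,LCAT,probable
case_0016,rater2,LCAT,probable
case_0017,rater1,LCAT,probable
case_0017,rater2,LCAT,probable
case_0018,rater1,LCAT,probable
case_0018,rater2,LCAT,probable
case_0019,rater1,LCAT,probable
case_0019,rater2,LCAT,probable
case_0020,rater1,LCAT,probable
case_0020,rater2,LCAT,probable
case_0021,rater1,LCAT,definite
case_0021,rater2,LCAT,probable
case_0022,rater1,LCAT,definite
case_0022,rater2,LCAT,definite
case_0023,rater1,LCAT,definite
case_0023,rater2,LCAT,definite
case_0024,rater1,LCAT,definite
case_0024,rater2,LCAT,definite
case_0025,rater1,LCAT,definite
case_0025,rater2,LCAT,definite
case_0026,rater1,LCAT,definite
case_0026,rater2,LCAT,definite
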