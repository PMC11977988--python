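product_type,commercial_name
"Watch1,1",1st generation
"Watch1,2",1st generation
"Watch2,6",Series 1
"Watch2,7",Series 1
"Watch2,3",Series 2
"Watch2,4",Series 2
"Watch3,1",Series 3
"Watch3,2",Series 3
"Watch3,3",Series 3
"Watch3,4",Series 3
"Watch4,1",Series 4
"Watch4,2",Series 4
"Watch4,3",Series 4
"Watch4,4",Series 4
"Watch5,1",Series 5
"Watch5,2",Series 5
"Watch5,3",Series 5
"Watch5,4",Series 5
"Watch5,9",SE
"Watch5,10",SE
"Watch5,11",SE
"Watch5,12",SE
"Watch6,1",Series 6
"Watch6,2",Series 6
"Watch6,3",Series 6
"Watch6,4",Series 6
"Watch6,6",Series 7
"Watch6,7",Series 7
"Watch6,8",Series 7
"Watch6,9",Series 7
"Watch6,10",SE 2
"Watch6,11",SE 2
"Watch6,12",SE 2
"Watch6,13",SE 2
"Watch6,14",Series 8
"Watch6,15",Series 8
"Watch6,16",Series 8
"Watch6,17",Series 8
"Watch6,18",Ultra
"Watch7,1",Series 9
"Watch7,2",Series 9
"Watch7,3",Series 9
"Watch7,4",Series 9
"Watch7,5",Ultra 2
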