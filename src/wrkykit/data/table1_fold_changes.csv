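regulation,pattern,gene,fc_LOI_LTD,fc_NOI_NTD,fc_LOI_NOI
Up-regulated,LOI/NOI and NOI/NTD,PvWRKY8,2.08,3.67,
Up-regulated,LOI/NOI and NOI/NTD,PvWRKY52,2.28,2.25,
Up-regulated,NOI/NTD,PvWRKY5,,3.53,
Up-regulated,NOI/NTD,PvWRKY39,,8.14,
Up-regulated,NOI/NTD,PvWRKY40,,2.09,
Up-regulated,NOI/NTD,PvWRKY59,,3.08,
Up-regulated,LOI/NOI,PvWRKY33,,,12.64
Down-regulated,LOI/LTD,PvWRKY60,-2.02,,
Down-regulated,LOI/NOI and NOI/NTD,PvWRKY6,-2.62,-5.39,
Down-regulated,LOI/NOI and NOI/NTD,PvWRKY77,-3.41,-12.10,
Down-regulated,NOI/NTD,PvWRKY24,,-3.43,
Down-regulated,NOI/NTD,PvWRKY38,,-2.40,
Down-regulated,NOI/NTD,PvWRKY58,,-2.09,
Down-regulated,LOI/NOI,PvWRKY1,,,-3.33
Down-regulated,LOI/NOI,PvWRKY3,,,-2.69
Down-regulated,LOI/NOI,PvWRKY21,,,-2.17
Down-regulated,LOI/NOI,PvWRKY43,,,-2.33
Down-regulated,LOI/LTD and LOI/NOI,PvWRKY2,-2.71,,-8.08
Down-regulated,LOI/LTD and LOI/NOI,PvWRKY28,-2.76,,-4.07
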