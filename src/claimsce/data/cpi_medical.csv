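year,index
2008,364.065
2009,375.613
2010,388.436
2011,400.258
2012,414.920
2013,425.134
2014,435.292
2015,446.752
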