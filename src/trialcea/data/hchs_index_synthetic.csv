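year,index
2008,255.3
2009,262.1
2010,268.6
2011,273.0
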