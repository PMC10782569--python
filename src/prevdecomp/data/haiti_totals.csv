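wave,tested,not_tested
2006,761,7866
2012,2806,8831
2016-17,2534,9358
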