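model,variance,loglik
Model-0,0.74,-2459.97
Model-I,0.59,-2280.88
Model-II,0.57,-2428.71
Model-III,0.49,-2265.05
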