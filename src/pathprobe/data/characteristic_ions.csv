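name,mz,polarity
coumaric acid,163.0377,negative
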