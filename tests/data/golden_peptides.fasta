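>toy|toy:t:6-14|intron|0
MEW
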