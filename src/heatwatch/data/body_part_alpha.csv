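body_part,alpha
rectal,0.0699
head,0.3094
torso,0.5067
hand,0.7665
foot,2.1807
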