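term	reason
brain	non-disease anatomical term
liver	non-disease anatomical term
consumption	ambiguous disease term
weak	ambiguous disease term
disorder	too general
disease	too general
deficiency	too general
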