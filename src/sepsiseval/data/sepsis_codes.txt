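# Explicit sepsis ICD-10 codes/prefixes (one per line).
# A40 streptococcal sepsis, A41 other sepsis, R57.2 septic shock.
A40
A41
R57.2
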