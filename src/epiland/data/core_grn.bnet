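# Nine-node core gene regulatory network of epithelial spontaneous
# immortalization. Synchronous Boolean rules selected by constraint
# search against the published attractor profiles, basin sizes and
# mutant conditions (see docs/methods.md).
targets, factors
NF-kB, NF-kB | ESE-2 | (Snai2 & p16)
ESE-2, !Snai2
Snai2, NF-kB & (Snai2 | !ESE-2)
p16, !Snai2 & ((p16 & (!E2F | !TELase)) | (!E2F & !TELase))
p53, p16 & !Snai2 & !TELase
Rb, p16 | !Cyclin
E2F, !Snai2 & ((Cyclin & (!Rb | !p53)) | (!Rb & !p53))
Cyclin, (!Snai2 & !p53) | (NF-kB & !p16 & (!p53 | E2F)) | (E2F & ESE-2 & NF-kB & !Snai2)
TELase, !ESE-2
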