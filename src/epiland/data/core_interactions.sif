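NF-kB	+	NF-kB
NF-kB	+	ESE-2
NF-kB	+	Snai2
NF-kB	+	Cyclin
NF-kB	-	p53
ESE-2	+	ESE-2
ESE-2	-	Snai2
ESE-2	+	Cyclin
ESE-2	-	TELase
ESE-2	+	NF-kB
Snai2	+	Snai2
Snai2	+	TELase
Snai2	-	ESE-2
Snai2	-	Cyclin
Snai2	-	E2F
Snai2	-	p16
Snai2	-	p53
Snai2	+	NF-kB
p16	+	p16
p16	+	p53
p16	+	Rb
p16	-	Cyclin
p16	+	NF-kB
p53	-	E2F
Rb	-	E2F
E2F	+	Cyclin
E2F	-	p16
Cyclin	-	Rb
Cyclin	+	E2F
TELase	-	p16
TELase	-	p53
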