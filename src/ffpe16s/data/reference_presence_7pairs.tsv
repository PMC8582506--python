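pair_id	genus	ish_ffpe	seq_ffpe	seq_ff
119	Bacteroides	-	+	+
121	Bacteroides	-	+	+
123	Bacteroides	+	+	+
124	Bacteroides	-	-	+
129	Bacteroides	+	+	+
135	Bacteroides	-	+	+
136	Bacteroides	+	+	+
119	Fusobacterium	+	-	-
121	Fusobacterium	-	-	-
123	Fusobacterium	+	+	+
124	Fusobacterium	+	-	+
129	Fusobacterium	+	-	+
135	Fusobacterium	-	-	-
136	Fusobacterium	+	-	+
119	Propionibacterium	+	+	+
121	Propionibacterium	+	+	+
123	Propionibacterium	+	+	+
124	Propionibacterium	+	+	+
129	Propionibacterium	+	+	+
135	Propionibacterium	+	+	+
136	Propionibacterium	+	+	-
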