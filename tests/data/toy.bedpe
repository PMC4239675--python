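chr1	99999	100000	chr2	299999	300000	toy	0	+	+
chr1	100000	100001	chr2	349999	350000	toy	0	-	+
chr1	199999	200000	chr2	399999	400000	toy	0	+	-
chr1	399999	400000	chr2	599999	600000	toy	0	+	-
chr1	406999	407000	chr2	606999	607000	toy	0	+	-
chr1	413999	414000	chr2	613999	614000	toy	0	+	-
chr1	420999	421000	chr2	620999	621000	toy	0	+	-
chr1	427999	428000	chr2	627999	628000	toy	0	+	-
chr1	434999	435000	chr2	634999	635000	toy	0	+	-
chr1	441999	442000	chr2	641999	642000	toy	0	+	-
chr1	448999	449000	chr2	648999	649000	toy	0	+	-
chr1	455999	456000	chr2	655999	656000	toy	0	+	-
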