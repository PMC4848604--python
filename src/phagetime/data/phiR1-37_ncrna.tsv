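# Novel ncRNA species reported from the bacteriophage phiR1-37 genome.
# Coordinates are 1-based inclusive on the phage genome; nine species lie on
# the strand opposite an annotated gene (putative antisense RNAs) and one in
# an intragenic region with no ORF possibilities.
name	start	end	strand	relation_text
misc_1	14254	14383	-	antisense to 3' end of g048
misc_2	17805	18199	+	antisense to 5' end of g055 and 3' end of g056
misc_3	32500	32820	-	antisense to 5' end of g077
misc_4	61640	61936	+	intragenic region between g099 and g100
misc_5	91090	91192	-	antisense to middle part of g144
misc_6	103380	103720	+	antisense to g157 and 5' end of g156
misc_7	148610	148960	+	antisense to 5' end of g207
misc_8	160970	161280	+	antisense to middle part of g230
misc_9	217379	217553	+	antisense to middle part of g295
misc_10	242633	242957	-	antisense to middle part of g326
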