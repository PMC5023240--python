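population	isolate	growth_relative_to_em	n_novel_expression	total_mutations	n_intergenic	n_coding	n_is_elements
F1	CM1727	1.96	149	11	2	8	2
F2	CM1730	2.15	12	4	2	1	1
F3	CM1139	2.44	17	11	5	5	2
F4	CM1145	2.50	217	9	4	4	2
F5	CM1739	2.09	42	11	5	5	6
F6	CM1742	2.09	47	11	2	8	3
F7	CM1745	2.16	21	9	2	6	2
F8	CM1748	2.11	197	18	8	8	6
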