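segment_id	stage	animal_id	total_length_um	has_head	head_diameter_um	neck_max_diameter_um	neck_length_um
seg1	glass	a1	1.2	1	0.8	0.4	0.3
seg1	glass	a1	1.2	1	0.8	0.4	0.3
seg1	glass	a1	1.2	1	0.8	0.4	0.3
seg1	glass	a1	1.2	1	0.8	0.4	0.3
seg1	glass	a1	2.0	1	0.5	0.2	1.5
seg1	glass	a1	2.0	1	0.5	0.2	1.5
seg1	glass	a1	2.0	1	0.5	0.2	1.5
seg1	glass	a1	0.7	0	0.0	0.0	0.0
seg3	elver	a2	1.2	1	0.8	0.4	0.3
seg3	elver	a2	2.0	1	0.5	0.2	1.5
seg3	elver	a2	0.7	0	0.0	0.0	0.0
seg3	elver	a2	12.0	0	0.0	0.0	0.0
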