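location	origin	n	n_pigmented	n_white
Edersee	G	13	10	3
Eulbach	G	22	19	3
Griebelschied	G	2	0	2
Hanstedt	G	6	1	5
Murowana	H	1	1	0
Weishauswald	G	6	5	1
Mueritz	H	3	2	1
Neuruppin	H	13	13	0
Pleizenhausen	G	1	0	1
Sababurg	G	29	24	5
Weilburg	G	2	2	0
Wolfshagen	H	4	3	1
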