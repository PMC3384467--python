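step_id	pathway	ec_number	cog_ids	description
ss01	starch-sucrose	3.2.1.26	COG1621	beta-fructofuranosidase (sucrose hydrolysis)
ss02	starch-sucrose	2.4.1.8	COG0058	maltose phosphorylase
ss03	starch-sucrose	5.4.2.2	COG1109	phosphoglucomutase
ss04	starch-sucrose	2.7.1.2	COG0837	glucokinase
gu01	glycolysis-upper	5.3.1.9	COG0166	glucose-6-phosphate isomerase
gu02	glycolysis-upper	2.7.1.11	COG0205	6-phosphofructokinase
gu03	glycolysis-upper	4.1.2.13	COG0191	fructose-bisphosphate aldolase
gu04	glycolysis-upper	5.3.1.1	COG0149	triosephosphate isomerase
gl01	glycolysis-lower	1.2.1.12	COG0057	glyceraldehyde-3-phosphate dehydrogenase
gl02	glycolysis-lower	2.7.2.3	COG0126	phosphoglycerate kinase
gl03	glycolysis-lower	5.4.2.11	COG0588	phosphoglycerate mutase
gl04	glycolysis-lower	4.2.1.11	COG0148	enolase
gl05	glycolysis-lower	2.7.1.40	COG0469	pyruvate kinase
gl06	glycolysis-lower	1.2.4.1	COG2609	pyruvate dehydrogenase complex E1
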