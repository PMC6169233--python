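name,concentration_ng_ml,sd_ng_ml,epa_priority,oncologic_level
Naphthalene,1617.2,341.2,+,
Phenanthrene,597.1,171.7,+,low
Fluoranthene,422.6,35.7,+,
Acenaphthene,404.7,96.4,+,low
Fluorene,321.2,188.5,+,
Pyrene,288.0,21.4,+,low
Carbazole,246.0,60.1,,
Dibenzofuran,207.7,82.9,,
1-Methylnaphthalene,161.5,31.7,,
Benz(a)anthracene,77.6,7.8,+,low-moderate
Anthracene,73.1,12.1,+,
Benzo(b)fluoranthene,66.1,4.8,+,moderate-high
Dibenzothiophene,63.4,49.8,,
Chrysene,62.0,4.7,+,
"1,2-Benzofluorene",46.5,4.1,,
"2,6-Dimethylnaphthalene",44.7,39.4,,
Benzo(a)pyrene,44.3,2.4,+,high
Retene,43.8,3.6,,
2-Methylphenanthrene,39.8,10.7,,
Benzo(e)pyrene,31.2,7.3,,
Benzo(k)fluoranthene,26.6,1.7,+,low-moderate
1-Methylphenanthrene,20.5,3.1,,
Acenaphthylene,17.0,8.5,+,
"Benzo(g,h,i)perylene",14.7,1.3,+,
Picene,14.2,1.2,,moderate
"3,4-Benzofluorene",9.0,3.0,,
Perylene,8.8,0.8,,low
Benzo(a)fluoranthene,6.9,0.7,,low-moderate
"Dibenz(a,l)pyrene",6.2,0.5,,high
"Indeno(1,2,3-c,d)pyrene",3.6,0.5,+,moderate
Benzo(b)chrysene,3.5,0.4,,
"Dibenz(a,j)anthracene",2.8,0.6,,moderate
"Dibenz(a,h)anthracene",2.8,0.6,+,high
Benzo(c)phenanthrene,2.4,0.3,,low-moderate
3-Methylcholanthrene,0.0,0.0,,
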