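country,group,unit_type,n_units,cumulative_cases_per_100k,mean_stringency,in_region_average
Burkina Faso,West Africa,Districts,70,31.2,43.6,True
Cote d'Ivoire,West Africa,Districts,113,83.1,44.6,True
Ghana,West Africa,Districts,260,172.6,48.5,True
Liberia,West Africa,Counties,15,34.7,65.1,True
Mali,West Africa,Districts,75,34.0,54.3,True
Niger,West Africa,Districts,72,13.2,32.4,True
Nigeria,West Africa,States,37,41.4,63.1,True
Ethiopia,Eastern Africa,Regions,12,105.4,65.9,True
Kenya,Eastern Africa,Counties,47,175.4,66.2,True
Tanzania,Eastern Africa,District councils,184,0.8,,False
Uganda,Eastern Africa,Districts,136,74.7,74.9,True
Zambia,Eastern Africa,Districts,116,109.5,46.1,True
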