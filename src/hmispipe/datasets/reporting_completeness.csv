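country,group,year,national_completeness,pct_districts_above_90
Burkina Faso,West Africa,2017,97,90
Burkina Faso,West Africa,2018,98,93
Burkina Faso,West Africa,2019,,
Burkina Faso,West Africa,2020,93,79
Cote d'Ivoire,West Africa,2017,90,59
Cote d'Ivoire,West Africa,2018,94,88
Cote d'Ivoire,West Africa,2019,97,96
Cote d'Ivoire,West Africa,2020,98,98
Liberia,West Africa,2017,,
Liberia,West Africa,2018,95,90
Liberia,West Africa,2019,95,88
Liberia,West Africa,2020,96,92
Ghana,West Africa,2017,93,77
Ghana,West Africa,2018,94,80
Ghana,West Africa,2019,95,87
Ghana,West Africa,2020,98,96
Mali,West Africa,2017,92,85
Mali,West Africa,2018,95,90
Mali,West Africa,2019,99,99
Mali,West Africa,2020,99,97
Niger,West Africa,2017,89,69
Niger,West Africa,2018,92,73
Niger,West Africa,2019,87,68
Niger,West Africa,2020,84,53
Nigeria,West Africa,2017,74,19
Nigeria,West Africa,2018,79,27
Nigeria,West Africa,2019,79,27
Nigeria,West Africa,2020,68,16
Ethiopia,Eastern Africa,2017,,
Ethiopia,Eastern Africa,2018,,
Ethiopia,Eastern Africa,2019,84,94
Ethiopia,Eastern Africa,2020,81,94
Kenya,Eastern Africa,2017,82,
Kenya,Eastern Africa,2018,92,75
Kenya,Eastern Africa,2019,94,79
Kenya,Eastern Africa,2020,95,89
Tanzania,Eastern Africa,2017,96,87
Tanzania,Eastern Africa,2018,97,92
Tanzania,Eastern Africa,2019,97,95
Tanzania,Eastern Africa,2020,98,98
Uganda,Eastern Africa,2017,88,59
Uganda,Eastern Africa,2018,89,61
Uganda,Eastern Africa,2019,89,62
Uganda,Eastern Africa,2020,84,74
Zambia,Eastern Africa,2017,95,100
Zambia,Eastern Africa,2018,96,98
Zambia,Eastern Africa,2019,93,75
Zambia,Eastern Africa,2020,96,87
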