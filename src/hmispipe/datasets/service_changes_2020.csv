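country,group,ANC1,ANC4,DELIV,CSEC,PENTA1,PENTA3,MEASLES,OPD,IPD
Burkina Faso,West Africa,7.1,-6.0,0.5,2.4,2.6,5.8,-0.4,-2.6,2.4
Cote d'Ivoire,West Africa,0.4,-3.6,-2.1,-4.9,,,,-12.4,-2.8
Ghana,West Africa,4.6,-0.4,-3.1,-2.5,-2.4,-2.6,-5.1,-21.0,-17
Liberia,West Africa,-5.4,-6.2,-4.8,-4.0,3.2,3.6,-3.0,-7.1,
Mali,West Africa,-3.0,-16.4,-3.4,-5.1,-12.4,-15.2,-16.4,-6.2,-8.2
Niger,West Africa,0,0.5,-5.7,-10.6,-0.3,-1.2,-1.4,1.7,-23.2
Ethiopia,Eastern Africa,-7.1,-4.8,-1.4,3.8,-4.5,-4.4,-3.2,-22.8,-25.1
Kenya,Eastern Africa,1.0,-8.9,-3.5,0.2,-1.5,1.9,7.2,-29.2,-24.8
Tanzania,Eastern Africa,-2.6,-8.2,-6.8,-0.8,-3.9,-5.7,-2.6,-3.3,-11.1
Uganda,Eastern Africa,-1.8,-0.8,-3.8,-9.4,-7.2,-5.3,-2.5,-8.9,-18.2
Zambia,Eastern Africa,-4.7,-17.5,-14.3,-20.2,-0.6,1.3,-5.4,-1.5,
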