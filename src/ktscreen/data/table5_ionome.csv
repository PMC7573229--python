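tissue,treatment,genotype,N (g/kg),P (g/kg),K (g/kg),Ca (g/kg),Mg (g/kg),Na (g/kg),Fe (mg/kg),Mn (mg/kg),Cu (mg/kg),Zn (mg/kg)
shoot,CK,KN9204,26.23Ab,8.59Aa,29.58Aa,3.94Aa,1.70Aa,2.58Ba,8.16Ab,9.23Aa,2.33Ab,31.83Aa
shoot,CK,BN207,31.82Aa,5.80Ab,26.60Ab,2.56Bb,1.55Aa,1.86Aa,18.19Aa,7.09Ab,5.82Aa,31.95Aa
shoot,LK,KN9204,21.76Ba,7.80Aa,7.05Ba,4.64Aa,1.98Aa,2.87Aa,7.03Ab,8.89Aa,1.98Ab,30.35Ba
shoot,LK,BN207,16.14Bb,3.57Bb,5.62Bb,3.86Aa,1.81Aa,2.05Ab,15.04Ba,6.31Ab,4.64Aa,29.81Ba
root,CK,KN9204,25.14Aa,4.21Aa,9.25Aa,2.63Aa,0.31Aa,2.65Aa,31.29Aa,4.58Ab,2.12Ab,35.06Aa
root,CK,BN207,23.37Ab,4.44Aa,7.00Ab,0.61Bb,0.29Aa,2.29Ba,23.77Ab,10.38Aa,6.10Aa,33.70Ab
root,LK,KN9204,22.39Aa,3.40Aa,4.81Ba,2.64Aa,0.32Aa,2.80Aa,30.39Aa,3.83Ab,1.86Ab,31.09Ba
root,LK,BN207,15.07Bb,0.70Bb,1.40Bb,1.35Ab,0.31Aa,2.89Aa,19.61Bb,8.89Aa,5.12Aa,27.30Bb
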