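genotype,tissue,protocol,analog,mean,sd,n,scale_applied,model_prediction
WT,beta,day0,BrdU,0.5,0.5,3,False,0.0
WT,beta,day1,BrdU,0.5,0.5,3,False,0.6
WT,beta,day2,BrdU,1.9,1.2,3,False,1.8
WT,beta,day14,BrdU,1.8,0.8,3,False,1.4
WT,beta,2-2-4,CldU,6.6,2.8,3,True,2.4
WT,beta,2-2-14,CldU,4.6,4.3,3,True,2.3
WT,beta,7-7-14,CldU,8.0,2.8,3,True,9.2
WT,beta,2-2-4,IdU,14.8,12.3,3,True,3.3
WT,beta,2-2-14,IdU,8.9,8.4,3,True,3.2
WT,beta,7-7-14,IdU,9.8,7.4,3,True,5.0
R24C,beta,day0,BrdU,1.3,0.6,3,False,0.5
R24C,beta,day1,BrdU,1.1,0.4,3,False,1.3
R24C,beta,day2,BrdU,2.9,1.3,3,False,2.3
R24C,beta,day14,BrdU,4.6,1.8,3,False,2.0
R24C,beta,2-2-4,CldU,3.2,0.5,3,True,3.5
R24C,beta,2-2-14,CldU,11.2,7.3,3,True,2.8
R24C,beta,7-7-14,CldU,19.8,12.0,3,True,24.4
R24C,beta,2-2-4,IdU,10.1,3.5,3,True,8.6
R24C,beta,2-2-14,IdU,23.0,11.3,3,True,6.8
R24C,beta,7-7-14,IdU,26.1,4.2,3,True,25.8
WT,duct,day0,BrdU,0.2,0.1,3,False,0.1
WT,duct,day1,BrdU,0.4,0.4,3,False,0.3
WT,duct,day2,BrdU,0.4,0.1,3,False,0.5
WT,duct,day14,BrdU,1.2,1.2,3,False,1.3
WT,duct,2-2-4,CldU,8.0,7.8,3,True,0.8
WT,duct,2-2-14,CldU,5.5,1.8,3,True,0.6
WT,duct,7-7-14,CldU,11.9,3.5,3,True,11.1
WT,duct,2-2-4,IdU,11.9,4.3,3,True,2.3
WT,duct,2-2-14,IdU,5.6,2.7,3,True,2.0
WT,duct,7-7-14,IdU,25.8,18.2,3,True,16.7
R24C,duct,day0,BrdU,1.3,0.6,3,False,0.0
R24C,duct,day1,BrdU,2.8,1.0,3,False,1.0
R24C,duct,day2,BrdU,12.9,0.1,3,False,12.5
R24C,duct,day14,BrdU,5.6,0.1,3,False,2.1
R24C,duct,2-2-4,CldU,7.9,1.7,3,True,12.1
R24C,duct,2-2-14,CldU,11.7,8.8,3,True,9.0
R24C,duct,7-7-14,CldU,19.5,14.8,3,True,43.6
R24C,duct,2-2-4,IdU,47.6,43.0,3,True,20.6
R24C,duct,2-2-14,IdU,9.0,0.7,3,True,15.3
R24C,duct,7-7-14,IdU,7.5,5.1,3,True,31.7
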