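# Published organ-mass comparison: reference masses (adult-female reference phantom for maternal organs; fetal reference masses for the fetus) against the pregnant model's voxel masses, with the printed percent differences.
block,organ,reference_g,new_g,printed_diff_pct
maternal,"Cartilage, trunk",313.61,313.61,0.0
maternal,"Breast, left, adipose tissue",150.0,489.73,226.48
maternal,"Breast, right, adipose tissue",150.0,512.11,241.4
maternal,Gall bladder wall,10.24,9.96,-2.74
maternal,Gall bladder contents,45.75,31.82,-30.45
maternal,Stomach wall,140.0,140.0,0.0
maternal,Stomach contents,230.01,165.84,-27.9
maternal,Small intestine wall,600.0,600.0,0.0
maternal,Small intestine contents,280.01,156.61,-44.07
maternal,Ascending colon wall,90.0,90.0,0.0
maternal,Ascending colon contents,100.01,86.42,-13.59
maternal,"Transverse colon wall, right",55.0,55.0,0.01
maternal,"Transverse colon contents, right",60.0,58.06,-3.23
maternal,"Transverse colon wall, left",55.0,54.79,-0.37
maternal,"Transverse colon contents, left",30.0,28.51,-4.96
maternal,Descending colon wall,90.0,90.0,0.0
maternal,Descending colon contents,50.0,49.0,-2.03
maternal,Sigmoid colon wall,45.01,45.01,-0.01
maternal,Sigmoid colon contents,80.0,79.01,-1.23
maternal,Rectum wall,25.0,24.85,-0.56
maternal,"Kidney, left, pelvis",149.48,149.48,0.0
maternal,"Kidney, right, pelvis",125.53,125.53,0.0
maternal,Liver,1400.0,1399.72,-0.02
maternal,"Lung, left, tissue",377.02,377.02,0.0
maternal,"Lung, right, tissue",472.03,471.85,-0.04
maternal,"Muscle, trunk",8518.22,8389.34,-1.51
maternal,Esophagus (wall),34.99,34.99,0.01
maternal,"Ovary, left",5.5,5.5,0.03
maternal,"Ovary, right",5.5,5.5,0.03
maternal,Pancreas,120.0,120.0,0.0
maternal,"Residual tissue, trunk",11803.12,14149.25,19.88
maternal,"Skin, trunk",1004.12,1114.05,10.95
maternal,Spleen,130.0,130.0,0.0
maternal,Urinary bladder wall,40.0,40.0,-0.01
maternal,Thyroid,17.0,17.0,0.0
maternal,Urinary bladder contents,200.0,226.53,13.26
maternal,Uterus,79.99,823.33,929.3
fetal,Amniotic fluid,,207.17,
fetal,Umbilical cord,,25.6,
fetal,Placenta,,1070.39,
fetal,Fetus,3500.0,3471.98,0.8
fetal,"Fetus, brain",370.0,370.0,0.0
fetal,"Fetus, skeleton",,204.31,
fetal,"Fetus, eyes",,4.13,
fetal,"Fetus, spinal cord",,5.43,
fetal,"Fetus, thyroid",1.3,1.3,0.24
fetal,"Fetus, lungs",60.0,59.87,0.21
fetal,"Fetus, thymus",13.0,13.0,-0.03
fetal,"Fetus, heart",20.0,20.0,0.01
fetal,"Fetus, liver",130.0,130.3,-0.23
fetal,"Fetus, kidneys",25.0,25.0,-0.02
fetal,"Fetus, adrenals",6.0,6.0,0.0
fetal,"Fetus, spleen",9.5,9.5,0.0
fetal,"Fetus, SI wall",,13.63,
fetal,"Fetus, SI contents",,11.39,
fetal,"Fetus, LI wall",,6.03,
fetal,"Fetus, LI contents",,5.95,
fetal,"Fetus, bladder wall",,9.44,
fetal,"Fetus, bladder contents",,27.22,
fetal,"Fetus, stomach wall",,10.15,
fetal,"Fetus, stomach contents",,3.86,
fetal,"Fetus, gall bladder wall",,0.72,
fetal,"Fetus, gall bladder contents",,0.72,
fetal,"Fetus, pancreas",5.0,4.99,0.11
fetal,"Fetus, soft tissue",,2299.96,
fetal,"Fetus, skin",,229.08,
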