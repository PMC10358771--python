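organ,model,dsc,mda_mm,hd95_mm,pvd_pct,sdsc,rapl_mm_per_cc
aorta,t1,0.96,0.5,1.62,-2.15,0.99,0.13
aorta,t2,0.91,1.05,2.64,-8.95,0.89,5.0
aorta,multi,0.94,0.75,2.11,-5.71,0.95,2.31
large_bowel,t1,0.85,3.8,18.97,0.27,0.73,9.54
large_bowel,t2,0.86,2.85,14.87,-4.51,0.77,7.9
large_bowel,multi,0.85,3.85,23.68,1.73,0.76,7.54
small_bowel,t1,0.85,2.38,9.39,-7.77,0.74,11.54
small_bowel,t2,0.84,3.42,19.52,-6.06,0.68,10.92
small_bowel,multi,0.84,2.81,14.51,-11.8,0.71,12.07
duodenum,t1,0.77,2.76,12.68,-18.8,0.72,22.34
duodenum,t2,0.73,3.01,12.69,-13.8,0.64,21.65
duodenum,multi,0.75,2.92,12.68,-13.5,0.68,21.79
esophagus,t1,0.7,2.26,8.87,-36.3,0.7,56.79
esophagus,t2,0.66,4.0,13.63,-39.4,0.62,67.31
esophagus,multi,0.71,2.8,10.02,-31.2,0.7,54.16
left_kidney,t1,0.97,0.51,1.62,-1.9,0.98,0.96
left_kidney,t2,0.95,0.9,2.92,-0.83,0.91,2.66
left_kidney,multi,0.96,0.69,2.12,-2.91,0.95,1.75
right_kidney,t1,0.97,0.55,1.69,-0.06,0.97,1.35
right_kidney,t2,0.95,0.84,2.6,-2.95,0.92,2.45
right_kidney,multi,0.96,0.71,2.1,-2.64,0.94,1.85
liver,t1,0.98,0.99,2.93,-1.64,0.91,0.139
liver,t2,0.96,1.63,5.64,-3.74,0.79,2.62
liver,multi,0.97,1.24,3.92,-2.22,0.86,1.92
pancreas,t1,0.82,1.92,6.8,-16.0,0.73,19.3
pancreas,t2,0.77,3.97,16.61,-21.7,0.63,22.8
pancreas,multi,0.81,2.01,6.57,-14.8,0.68,18.24
spinal_cord,t1,0.8,1.2,3.01,-12.0,0.87,16.54
spinal_cord,t2,0.8,1.23,3.03,-19.7,0.82,20.86
spinal_cord,multi,0.8,1.21,3.18,-17.8,0.85,18.74
spleen,t1,0.98,0.57,1.8,-1.97,0.97,0.721
spleen,t2,0.96,1.01,3.17,-2.73,0.9,1.99
spleen,multi,0.97,0.97,3.86,-1.22,0.93,1.26
stomach,t1,0.93,1.44,4.66,-3.95,0.81,5.45
stomach,t2,0.92,1.62,5.19,-4.21,0.76,4.85
stomach,multi,0.93,1.5,4.66,-5.37,0.79,5.38
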