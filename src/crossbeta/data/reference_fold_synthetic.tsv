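# Synthetic reference conformation of the fibril-core construct
# (residues 441-460) used as planted ground truth for the
# emulated dihedral-prediction tables.  Satisfies the ten printed
# unambiguous contacts and the in-register stacking restraints
# exactly (H-bond components within ~0.07 A), with beta-region
# backbone torsions in the three strand interiors; NOT the
# deposited structure.
residue	angle	degrees
441	psi	145.132173
441	chi1	-2.890640
442	phi	-132.670792
442	psi	97.519423
442	chi1	118.110132
442	chi2	-170.528784
443	phi	-148.110109
443	psi	159.289139
443	chi1	72.605107
443	chi2	168.639831
444	phi	-108.659887
444	psi	106.954282
444	chi1	-87.579853
444	chi2	33.435709
445	phi	-142.387264
445	psi	160.287360
445	chi1	44.013054
446	phi	-101.770071
446	psi	-98.577695
446	chi1	-151.213937
447	phi	-85.360529
447	psi	95.604899
447	chi1	129.412505
447	chi2	47.550107
447	chi3	20.145729
448	phi	-129.316298
448	psi	167.787012
448	chi1	-38.887334
449	phi	-87.440342
449	psi	179.381841
449	chi1	-176.305646
449	chi2	66.307445
449	chi3	-169.887135
450	phi	-70.191936
450	psi	170.313448
450	chi1	147.247017
450	chi2	-88.274181
451	phi	-112.575171
451	psi	115.307199
452	phi	118.815559
452	psi	-139.462666
452	chi1	-117.187248
452	chi2	137.638746
453	phi	-70.365824
453	psi	-97.210068
453	chi1	-73.307674
453	chi2	-169.768552
454	phi	66.476889
454	psi	118.978678
454	chi1	123.024040
454	chi2	98.566244
455	phi	-129.835176
455	psi	122.908054
455	chi1	-131.910518
456	phi	-114.613351
456	psi	115.680847
456	chi1	-93.611049
456	chi2	29.354537
457	phi	-125.788947
457	psi	145.229577
457	chi1	29.983441
458	phi	-145.217634
458	psi	137.576733
458	chi1	-107.472946
459	phi	-130.727372
459	psi	100.709258
459	chi1	36.766428
460	psi	-97.209601
0	orient_rx	-72.000256
0	orient_ry	-50.830174
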