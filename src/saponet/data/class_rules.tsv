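class_label	diagnostic_ions	characteristic_losses	required_diag_matches	ion_weight	loss_weight
PPD	783.4992;621.4428	162.0528;146.0579	1	2.0	1.0
PPT	799.4928;637.4374;475.3813	162.0528;146.0579	1	2.0	1.0
OLE	793.4468;475.3813;455.3555	162.0528;146.0579	1	2.0	1.0
polygala-saponin	679.3759;455.3189	162.0528;146.0579	1	2.0	1.0
oligosaccharide-ester	137.0248;239.0566	162.0528	1	2.0	1.0
xanthone	297.0414;315.0519	132.0423;150.0528;162.0528	1	2.0	1.0
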