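case_id	cell_line	gd_status	volume_mm3_Optical	volume_mm3_T1	volume_mm3_T2	volume_mm3_T1+T2	volume_mm3_PET	volume_mm3_MRI+PET	sensitivity_T1	sensitivity_T2	sensitivity_T1+T2	sensitivity_PET	sensitivity_MRI+PET	specificity_T1	specificity_T2	specificity_T1+T2	specificity_PET	specificity_MRI+PET	dice_T1	dice_T2	dice_T1+T2	dice_PET	dice_MRI+PET	max_surface_distance_mm_T1	max_surface_distance_mm_T2	max_surface_distance_mm_T1+T2	max_surface_distance_mm_PET	max_surface_distance_mm_MRI+PET
tumor01	GB126	1	161	122	101	128	185	191	0.74	0.62	0.77	0.87	0.91	0.99	1	0.99	0.91	0.91	0.84	0.76	0.86	0.81	0.83	1.6	1.8	1.6	2.0	2.0
tumor02	GB126	1	86	61	52	63	112	117	0.68	0.59	0.70	0.84	0.89	1	1	1	0.93	0.93	0.80	0.74	0.81	0.73	0.75	1.1	1.1	1.1	2.0	2.0
tumor03	GB126	1	124	69	58	81	151	153	0.53	0.44	0.61	0.90	0.91	0.99	0.99	0.99	0.92	0.92	0.68	0.60	0.74	0.81	0.81	2.6	2.9	2.6	1.8	1.8
tumor04	U87	1	104	89	122	133	211	226	0.76	0.79	0.84	0.93	0.95	0.99	0.94	0.93	0.82	0.80	0.82	0.72	0.74	0.61	0.60	1.2	2.1	2.1	2.3	2.3
tumor05	GB187	0	104	0	72	72	161	172	0	0.53	0.53	0.85	0.89	1	0.97	0.97	0.88	0.87	0	0.63	0.63	0.67	0.67	nd	2.7	2.7	2.8	2.8
tumor06	GB187	0	76	0	60	60	87	109	0	0.52	0.52	0.56	0.73	1	0.96	0.96	0.91	0.90	0	0.58	0.58	0.53	0.60	nd	3.2	3.2	3.1	3.1
tumor07	GB187	0	30	0	28	28	29	47	0	0.73	0.73	0.46	0.88	1	0.97	0.97	0.93	0.91	0	0.76	0.76	0.47	0.69	nd	1.2	1.2	2.0	2.0
tumor08	GB187	0	63	0	60	60	69	89	0	0.63	0.63	0.67	0.80	1	0.96	0.96	0.95	0.93	0	0.64	0.64	0.63	0.66	nd	1.8	1.8	2.4	2.4
tumor09	U251	0	64	0	94	94	120	133	0	0.71	0.71	0.82	0.86	1	0.89	0.89	0.84	0.82	0	0.58	0.58	0.57	0.56	nd	2.4	2.4	2.4	2.4
tumor10	U251	0	22	0	8	8	0	8	0	0.24	0.24	0	0.24	1	0.99	0.99	1	0.99	0	0.35	0.35	0	0.35	nd	3.1	3.1	nd	3.1
tumor11	GB7	0	132	0	71	71	0	71	0	0.37	0.37	0	0.37	1	0.97	0.97	1	0.97	0	0.47	0.47	0	0.47	nd	7.6	7.6	nd	7.6
tumor12	GB7	0	131	0	39	39	0	39	0	0.21	0.21	0	0.21	1	0.98	0.98	1	0.98	0	0.32	0.32	0	0.32	nd	8.6	8.6	nd	8.6
tumor13	GB94	0	20	0	57	57	0	57	0	0.35	0.35	0	0.35	1	0.93	0.93	1	0.93	0	0.18	0.18	0	0.18	nd	4.7	4.7	nd	4.7
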