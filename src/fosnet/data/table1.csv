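# n_per_group: Naive=6,MPTP=6,Acu=6,Sham=6
region,full_name,subdivision,Naive_mean,Naive_sem,MPTP_mean,MPTP_sem,Acu_mean,Acu_sem,Sham_mean,Sham_sem
IC,Insular cortex,cortex,12.4,0.6,8.7,0.9,11.0,0.9,9.1,0.2
PFC,Prefrontal cortex,cortex,17.5,1.1,16.7,0.7,21.7,2.0,20.9,1.4
Cg1,"Cingulate cortex, area 1",cortex,11.3,1.7,10.7,1.4,10.0,1.5,9.3,1.3
Cg2,"Cingulate cortex, area 2",cortex,12.8,2.3,13.8,1.1,15.6,2.3,12.5,1.0
M1,Primary motor cortex,cortex,31.1,0.5,23.0,1.7,30.9,1.2,21.1,2.0
S1,Primary somatosensory cortex,cortex,36.3,2.2,31.0,2.5,29.0,1.5,28.9,2.4
DLS,Dorsolateral striatum,basal_ganglia,5.6,1.0,9.1,0.5,3.9,0.4,10.0,1.8
DMS,Dorsomedial striatum,basal_ganglia,8.1,1.2,20.9,4.7,8.1,1.3,22.0,3.2
AcbC,Accumbens nucleus core,basal_ganglia,29.5,1.8,38.0,2.9,26.4,1.2,34.8,1.6
AcbSh,Accumbens nucleus shell,basal_ganglia,12.8,1.2,17.9,3.2,8.0,0.6,12.8,1.0
Gp,Globus pallidus,basal_ganglia,27.0,2.1,32.9,1.3,20.1,2.5,27.1,4.2
CA1,Field CA1 of hippocampus,hippocampus,19.1,1.6,18.2,1.8,21.8,0.8,19.9,2.1
CA2,Field CA2 of hippocampus,hippocampus,5.5,0.9,7.5,1.3,6.2,1.1,6.8,0.9
CA3,Field CA3 of hippocampus,hippocampus,13.4,1.4,12.0,0.6,16.9,0.9,14.2,1.0
DG,Dentate gyrus,hippocampus,16.7,0.9,13.7,0.6,20.2,1.0,16.1,1.4
VA,Ventral anterior thalamic nucleus,thalamus,6.3,1.4,6.5,0.5,5.5,1.0,5.9,0.5
VL,Ventral lateral thalamic nucleus,thalamus,5.6,0.9,5.6,0.6,4.2,0.4,4.3,0.3
CM,Central medial thalamic nucleus,thalamus,11.6,1.2,14.1,1.4,6.7,1.5,7.7,1.6
Sm,Submedius thalamic nucleus,thalamus,15.9,1.5,20.3,3.3,19.1,2.1,17.9,1.2
LH,Lateral hypothalamus,hypothalamus,23.9,1.2,22.9,0.9,28.7,1.8,21.9,0.6
PVN,Paraventricular hypothalamic nucleus,hypothalamus,57.2,7.5,39.8,7.1,53.8,4.4,42.6,5.4
Arc,Arcuate hypothalamic nucleus,hypothalamus,32.8,6.4,36.8,5.9,26.6,1.0,31.3,2.1
AHA,Anterior hypothalamic area,hypothalamus,30.2,4.0,23.5,4.0,26.2,2.7,26.8,3.2
PHA,Posterior hypothalamic area,hypothalamus,26.9,4.7,24.6,2.4,29.6,2.8,24.2,2.3
VTA,Ventral tegmental area,midbrain,4.1,0.7,5.3,0.6,4.7,0.6,4.0,0.2
SNpc,Substantia nigra pars compacta,midbrain,1.3,0.3,2.7,0.2,1.2,0.2,2.1,0.4
SNr,Substantia nigra reticular,midbrain,3.8,0.6,4.8,0.8,4.4,0.5,4.4,1.1
PPTg,Pedunculopontine tegmental nucleus,midbrain,10.9,0.8,10.9,0.9,12.5,0.6,12.2,1.4
LC,Locus coeruleus,hindbrain,6.2,0.5,6.6,0.3,7.3,0.6,6.8,0.6
Sol,Nucleus of the solitary tract,hindbrain,3.7,0.2,4.3,0.5,6.4,0.6,5.5,0.5
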