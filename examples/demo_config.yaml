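# Full synthetic pipeline run: phantom + dynamic PET -> SUVR/R1/PVC ->
# voxel-wise group stats -> cohort simulation -> five-model SEM comparison.
out_dir: scratch/demo_run
seed: 7
stages: [simulate, quantify, stats, sem]
tracer: martinostat
grid_size: 24
voxel_size_mm: 2.0
n_per_group: 8
group_effect: -0.12
image_noise_sd: 0.05
fdr_q: 0.05
alpha: 0.05
psf_fwhm_mm: 8.0
cohort_sizes: [25, 28, 15, 26]
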