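# Cellular constants: Mus musculus 3T3 fibroblasts.
organism_label: "M. musculus (3T3)"
N_m: 180000           # mRNAs per cell
N_p: 6.0e+9           # proteins per cell (3e6 per um^3 x 2000 um^3)
mu: 0.03              # growth rate, h^-1 (24 h cell cycle)
alpha_deg: 0.01       # protein degradation, h^-1 (48 h half-life, division removed)
alpha_p: 0.04         # protein decay = degradation + dilution, h^-1
alpha_m: 0.14         # median mRNA decay, h^-1
cv0: 0.3              # noise floor, borrowed from H. sapiens (unmeasured in mouse)
l_m: 25000            # typical pre-mRNA length, nt (cancels out of the boundary prediction)
total_transcription: 2.52e+4   # N_m * alpha_m, mRNA h^-1
beta_p_max: 3.0e+3    # top percentile of measured translation rates
rho: 1.0
reference:
  measured_k: 44.0
  measured_k_se: 3.0
  predicted_k: 29.0
  predicted_k_se: 8.0
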