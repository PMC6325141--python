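# Cellular constants: Homo sapiens HeLa cells.
organism_label: "H. sapiens (HeLa)"
N_m: 225000           # mRNAs per cell (scaled from 3T3 by cell volume, 2500/2000)
N_p: 7.5e+9           # proteins per cell (3e6 per um^3 x 2500 um^3)
mu: 0.03              # growth rate, h^-1 (22 h division time)
alpha_deg: 0.02       # protein degradation, h^-1
alpha_p: 0.05         # protein decay = degradation + dilution, h^-1
alpha_m: 0.06         # median mRNA decay, h^-1 (11.4 h half-life)
cv0: 0.3              # noise floor
l_m: 25000            # typical pre-mRNA length, nt (cancels out of the boundary prediction)
total_transcription: 1.35e+4   # N_m * alpha_m, mRNA h^-1
beta_p_max: 5.1e+3    # top percentile of measured translation rates
rho: 1.0
reference:
  measured_k: 66.0
  measured_k_se: 4.0
  predicted_k: 60.0
  predicted_k_se: 17.0
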