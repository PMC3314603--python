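# Default selection configuration for a low-density bovine imputation panel.
#
# Round 1 scores candidates on European populations: criterion A is the
# weighted mean MAF over twelve breeds with Holstein double-weighted,
# criterion B the minimum MAF over six major dairy breeds.  Round 2 rescores
# the round-1 survivors adding North American / Oceanian populations:
# criterion A is the mean MAF over five breeds (incl. one indicine),
# criterion B the minimum over three.  Breed lists and weights are fully
# user-editable; chromosome lengths must be supplied by the caller (the
# toolkit does not embed a genome assembly).
window_size: 500000
picks_per_window: 1
terminal_picks: 2
compat_target: 2000
compat_radius: 250000
max_gap: 1000000
round1:
  mean_breeds:
    - Holstein
    - Montbeliarde
    - Normande
    - Jersey
    - Brown Swiss
    - Norwegian Red
    - Swedish Red and White
    - Finnish Ayrshire
    - Charolais
    - Limousin
    - Blonde d'Aquitaine
    - Maine Anjou
  mean_weights:
    Holstein: 2.0
  min_breeds:
    - Holstein
    - Montbeliarde
    - Normande
    - Jersey
    - Brown Swiss
    - Norwegian Red
round2:
  mean_breeds:
    - Holstein
    - Jersey
    - Brown Swiss
    - Angus
    - Brahman
  mean_weights: {}
  min_breeds:
    - Jersey
    - Brown Swiss
    - Angus
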