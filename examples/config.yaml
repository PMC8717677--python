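n_patients: 2000
success_fraction: 0.5
bp_noise_sd: 5.0
seed: 42
attribute_specs:
- attribute_name: HCT
  distribution_family: two_block
  successful_params:
    loc: 0.25
    scale: 0.15
  unsuccessful_params:
    loc: 0.75
    scale: 0.15
  crossover: 0.58
- attribute_name: HB
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4881
    scale: 0.15
  unsuccessful_params:
    loc: 0.5566
    scale: 0.15
  crossover: null
- attribute_name: PLT
  distribution_family: truncated_normal
  successful_params:
    loc: 0.362
    scale: 0.15
  unsuccessful_params:
    loc: 0.3404
    scale: 0.15
  crossover: null
- attribute_name: Cr
  distribution_family: truncated_normal
  successful_params:
    loc: 0.2005
    scale: 0.15
  unsuccessful_params:
    loc: 0.105
    scale: 0.15
  crossover: null
- attribute_name: Urea
  distribution_family: truncated_normal
  successful_params:
    loc: 0.2897
    scale: 0.15
  unsuccessful_params:
    loc: 0.2017
    scale: 0.15
  crossover: null
- attribute_name: UA
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4559
    scale: 0.15
  unsuccessful_params:
    loc: 0.4466
    scale: 0.15
  crossover: null
- attribute_name: Cys
  distribution_family: truncated_normal
  successful_params:
    loc: 0.2732
    scale: 0.15
  unsuccessful_params:
    loc: 0.1701
    scale: 0.15
  crossover: null
- attribute_name: TC
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4314
    scale: 0.15
  unsuccessful_params:
    loc: 0.4025
    scale: 0.15
  crossover: null
- attribute_name: LDL
  distribution_family: truncated_normal
  successful_params:
    loc: 0.3545
    scale: 0.15
  unsuccessful_params:
    loc: 0.3295
    scale: 0.15
  crossover: null
- attribute_name: HDL
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4154
    scale: 0.15
  unsuccessful_params:
    loc: 0.4146
    scale: 0.15
  crossover: null
- attribute_name: K
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4428
    scale: 0.15
  unsuccessful_params:
    loc: 0.4324
    scale: 0.15
  crossover: null
- attribute_name: Na
  distribution_family: truncated_normal
  successful_params:
    loc: 0.343
    scale: 0.15
  unsuccessful_params:
    loc: 0.3483
    scale: 0.15
  crossover: null
- attribute_name: FPG
  distribution_family: truncated_normal
  successful_params:
    loc: 0.2601
    scale: 0.15
  unsuccessful_params:
    loc: 0.257
    scale: 0.15
  crossover: null
- attribute_name: Age
  distribution_family: truncated_normal
  successful_params:
    loc: 0.5286
    scale: 0.15
  unsuccessful_params:
    loc: 0.5916
    scale: 0.15
  crossover: null
- attribute_name: Sex
  distribution_family: truncated_normal
  successful_params:
    loc: 0.5044
    scale: 0.15
  unsuccessful_params:
    loc: 0.411
    scale: 0.15
  crossover: null
- attribute_name: SBP
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4109
    scale: 0.15
  unsuccessful_params:
    loc: 0.3182
    scale: 0.15
  crossover: null
- attribute_name: DBP
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4447
    scale: 0.15
  unsuccessful_params:
    loc: 0.3874
    scale: 0.15
  crossover: null
- attribute_name: PP
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4161
    scale: 0.15
  unsuccessful_params:
    loc: 0.3527
    scale: 0.15
  crossover: null
- attribute_name: HR
  distribution_family: truncated_normal
  successful_params:
    loc: 0.4134
    scale: 0.15
  unsuccessful_params:
    loc: 0.3949
    scale: 0.15
  crossover: null
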