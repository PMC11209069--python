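site:
  area:
    value: 39000.0
    unit: km^2
  mean_depth:
    value: 7.0
    unit: m
  precipitation:
    value: 397.0
    unit: mm/yr
  evaporation:
    value: 35.0
    unit: km^3/yr
  seawater_outflow:
    value: 54.4
    unit: km^3/yr
  seawater_inflow:
    value: 37.0
    unit: km^3/yr
  water_tss:
    value: 19.1
    unit: mg/L
  water_tss_oc:
    value: 0.165
    unit: fraction
  sedimentation_rate:
    value: 1.66
    unit: g/m^2/day
  resuspension_fraction:
    value: 0.64
    unit: fraction
  sediment_oc:
    value: 0.0242
    unit: fraction
  mean_temperature:
    value: 13.3
    unit: degC
  wind_speed:
    value: 8.25
    unit: m/s
  rivers:
  - name: Don
    discharge:
      value: 22.0
      unit: km^3/yr
    tss:
      value: 18.1
      unit: mg/L
    oc:
      value: 0.046
      unit: fraction
  - name: Kuban
    discharge:
      value: 11.0
      unit: km^3/yr
    tss:
      value: 125.0
      unit: mg/L
    oc:
      value: 0.046
      unit: fraction
hg_inputs:
  rain_thg:
    value: 240.0
    unit: ng/L
  seawater_thg:
    value: 9.5
    unit: ng/L
  atmospheric_thg:
    value: 6.0
    unit: ng/m^3
  river_thg:
    Don:
      value: 520.0
      unit: ng/L
    Kuban:
      value: 10.0
      unit: ng/L
  riverine_total_override:
    value: 9059.7
    unit: kg/yr
    provenance: reported-total
model_parameters:
  kd:
    value: 9.689719834647372
    unit: L/g
    provenance: calibrated
  k_vol:
    value: 0.3043572987101984
    unit: m/h
    provenance: calibrated
  scavenging_ratio:
    value: 39999.99999999999
    unit: dimensionless
    provenance: calibrated
  sediment_active_depth:
    value: 0.03
    unit: m
  sediment_porosity:
    value: 0.75
    unit: fraction
  sediment_solids_density:
    value: 2.4
    unit: g/cm^3
  sediment_diffusion:
    value: 0.0
    unit: m^3/yr
  include_seawater_inflow_load: false
  species_ratios:
    water:
      hg0: 0.02
      mehg: 0.05
      residual: 0.93
    sediment:
      hg0: 0.0
      mehg: 0.01
      residual: 0.99
    air:
      hg0: 1.0
      mehg: 0.0
      residual: 0.0
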