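# snrk1kin default parameterization (calibrated feeding-experiment defaults)
# concentrations in umol/gFW; 1 umol/gFW == 1 mM (1 gFW ~ 1 mL)
parameters:
  vmax_suc_import:
    value: 2.5
    unit: umol/gFW/h
    lower: 0.1
    upper: 25.0
    description: max sucrose uptake rate
  km_suc_import:
    value: 5.0
    unit: mM
    lower: 0.5
    upper: 50.0
    description: uptake affinity for external sucrose
  suc_external:
    value: 15.0
    unit: mM
    lower: 0.0
    upper: 100.0
    description: external sucrose during feeding
  v_cfbpase:
    value: 0.3
    unit: umol/gFW/h
    lower: 0.0
    upper: 2.0
    description: constant cFBPase input flux to F6P
  k_pgi:
    value: 2.5
    unit: 1/h
    lower: 0.01
    upper: 250.0
    description: phosphoglucoisomerase F6P->G6P
  k_pgm:
    value: 4.4
    unit: 1/h
    lower: 0.01
    upper: 440.0
    description: phosphoglucomutase G6P->G1P
  k_ugpase:
    value: 15.4
    unit: 1/h
    lower: 0.01
    upper: 1540.0
    description: UGPase G1P->UDPG
  k_tpp:
    value: 407.0
    unit: 1/h
    lower: 0.01
    upper: 2000.0
    description: trehalose-6-phosphate phosphatase T6P->Tre
  k_susy:
    value: 0.0126
    unit: 1/h
    lower: 1.0e-05
    upper: 5.0
    description: sucrose synthase cleavage Suc->Fru+UDPG
  k_sps:
    value: 2980000.0
    unit: 1/h
    lower: 1000000.0
    upper: 6000000.0
    description: SPS turnover constant (vmax_SPS/E_total)
  km_sps_f6p:
    value: 0.316
    unit: mM
    lower: 0.01
    upper: 10.0
    description: SPS affinity for F6P
  km_sps_udpg:
    value: 1.9
    unit: mM
    lower: 0.01
    upper: 10.0
    description: SPS affinity for UDPG
  e_sps_total:
    value: 8.5e-06
    unit: umol/gFW
    lower: 5.0e-06
    upper: 2.0e-05
    description: total SPS peptide amount
  vmax_snrk1:
    value: 1.35
    unit: umol/gFW/h
    lower: 0.1
    upper: 13.5
    description: max SPS phosphorylation rate by SnRK1
  km_snrk1:
    value: 1.0e-07
    unit: mM
    lower: 1.0e-09
    upper: 1.0e-05
    description: SnRK1 affinity for active SPS peptide
  ki_t6p:
    value: 0.005
    unit: mM
    lower: 0.0005
    upper: 0.05
    description: SnRK1 inhibition constant for T6P
  ki_g1p:
    value: 0.48
    unit: mM
    lower: 0.048
    upper: 4.8
    description: SnRK1 inhibition constant for G1P
  ki_g6p:
    value: 1.5
    unit: mM
    lower: 1.0
    upper: 15.0
    description: SnRK1 inhibition constant for G6P (>1 mM)
  k_partial:
    value: 0.29
    unit: '-'
    lower: 0.01
    upper: 1.0
    description: partial-inhibition ratio for T6P
  vmax_pp:
    value: 1.41
    unit: umol/gFW/h
    lower: 0.1
    upper: 13.8
    description: max SPS dephosphorylation rate by PP
  km_pp:
    value: 5.0e-08
    unit: umol/gFW
    lower: 1.0e-09
    upper: 1.0e-05
    description: PP affinity for inactive SPS peptide
  vmax_tps:
    value: 2.26
    unit: umol/gFW/h
    lower: 0.001
    upper: 10.0
    description: max T6P synthesis rate (TPS)
  km_tps_g6p:
    value: 0.131
    unit: mM
    lower: 0.01
    upper: 10.0
    description: TPS affinity for G6P
  km_tps_udpg:
    value: 4.24
    unit: mM
    lower: 0.01
    upper: 10.0
    description: TPS affinity for UDPG
  vmax_trehalase:
    value: 0.716
    unit: umol/gFW/h
    lower: 0.001
    upper: 10.0
    description: max trehalose cleavage rate
  km_trehalase:
    value: 0.053
    unit: mM
    lower: 0.001
    upper: 5.0
    description: trehalase affinity for Tre
  vmax_inv:
    value: 1.68
    unit: umol/gFW/h
    lower: 0.05
    upper: 15.0
    description: max sucrose cleavage rate (Inv)
  km_inv:
    value: 1.78
    unit: mM
    lower: 0.1
    upper: 50.0
    description: invertase affinity for Suc
  ki_inv_glc:
    value: 1000.0
    unit: mM
    lower: 1.0
    upper: 10000.0
    description: non-competitive product inhibition by Glc
  ki_inv_fru:
    value: 1000.0
    unit: mM
    lower: 1.0
    upper: 10000.0
    description: competitive product inhibition by Fru
  vmax_glck:
    value: 0.846
    unit: umol/gFW/h
    lower: 0.01
    upper: 10.0
    description: max glucokinase rate
  km_glck:
    value: 0.12
    unit: mM
    lower: 0.01
    upper: 5.0
    description: glucokinase affinity for Glc
  ki_glck_g6p:
    value: 1.97
    unit: mM
    lower: 0.01
    upper: 50.0
    description: non-competitive inhibition of GlcK by G6P
  vmax_frck:
    value: 0.799
    unit: umol/gFW/h
    lower: 0.01
    upper: 10.0
    description: max fructokinase rate
  km_frck:
    value: 0.228
    unit: mM
    lower: 0.01
    upper: 5.0
    description: fructokinase affinity for Fru
  ki_frck_f6p:
    value: 0.3
    unit: mM
    lower: 0.01
    upper: 50.0
    description: non-competitive inhibition of FrcK by F6P
  vmax_suc_export:
    value: 2.44
    unit: umol/gFW/h
    lower: 0.1
    upper: 25.0
    description: max sucrose export rate
  km_suc_export:
    value: 4.59
    unit: mM
    lower: 0.1
    upper: 50.0
    description: export affinity for Suc
  steady_inv_vmax_factor:
    value: 0.47
    unit: '-'
    lower: 0.01
    upper: 1.0
    description: vmax_inv scale for steady variant
  steady_inv_km_factor:
    value: 3.22
    unit: '-'
    lower: 1.0
    upper: 100.0
    description: km_inv scale for steady variant
  steady_inv_ki_glc_factor:
    value: 0.027
    unit: '-'
    lower: 0.0001
    upper: 1.0
    description: ki_inv_glc scale for steady variant
  steady_inv_ki_fru_factor:
    value: 0.00308
    unit: '-'
    lower: 0.0001
    upper: 1.0
    description: ki_inv_fru scale for steady variant
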