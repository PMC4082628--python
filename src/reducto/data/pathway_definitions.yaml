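# Curated carbohydrate-catabolism pathway definitions for the 14 substrates
# of the fermentation panel.  Each substrate requires every listed group
# (AND); a group is satisfied by any one of its alternative genes (OR).
# Gene lists are literature-style and editable — they are a working fixture
# for pathway-completeness logic, NOT an authoritative metabolic
# reconstruction.  Transporter groups are flagged.
substrates:
  Galactose:
    groups:
      - {name: galactose_uptake, transporter: true, genes: [galP]}
      - {name: galactokinase, genes: [galK]}
      - {name: gal1P_uridylyltransferase, genes: [galT]}
      - {name: UDP_glucose_epimerase, genes: [galE]}
  D-glucose:
    groups:
      - {name: glucose_uptake, transporter: true, genes: [ptsG, glcU]}
      - {name: glucokinase, genes: [glk]}
  D-fructose:
    groups:
      - {name: fructose_PTS, transporter: true, genes: [fruA]}
      - {name: fructose1P_kinase, genes: [fruK]}
  D-mannose:
    groups:
      - {name: mannose_PTS, transporter: true, genes: [manX, manY, manZ]}
      - {name: mannose6P_isomerase, genes: [manA]}
  N-acetylglucosamine:
    groups:
      - {name: nag_PTS, transporter: true, genes: [nagE]}
      - {name: nag6P_deacetylase, genes: [nagA]}
      - {name: glucosamine6P_deaminase, genes: [nagB]}
  Amygdalin:
    groups:
      - {name: beta_glucoside_PTS, transporter: true, genes: [bglP]}
      - {name: phospho_beta_glucosidase, genes: [bglB, bglA]}
  Arbutin:
    groups:
      - {name: beta_glucoside_PTS, transporter: true, genes: [bglP]}
      - {name: phospho_beta_glucosidase, genes: [bglA]}
  Esculin:
    groups:
      - {name: beta_glucoside_PTS, transporter: true, genes: [bglP]}
      - {name: phospho_beta_glucosidase, genes: [bglB]}
  Salicin:
    groups:
      - {name: beta_glucoside_PTS, transporter: true, genes: [bglP]}
      - {name: phospho_beta_glucosidase, genes: [bglB]}
  Cellobiose:
    groups:
      - {name: cellobiose_PTS, transporter: true, genes: [celB]}
      - {name: phospho_beta_glucosidase, genes: [bglB]}
  Maltose:
    groups:
      - {name: maltose_uptake, transporter: true, genes: [malP, malE]}
      - {name: maltose_phosphorylase, genes: [mapA]}
  Lactose:
    groups:
      # antiporter OR lactose PTS: either route imports lactose
      - {name: lactose_uptake, transporter: true, genes: [lacS, lacE]}
      # beta-galactosidase OR phospho-beta-galactosidase
      - {name: lactose_hydrolysis, genes: [lacZ, lacG]}
  Sucrose:
    groups:
      - {name: sucrose_PTS, transporter: true, genes: [scrA]}
      - {name: sucrose6P_hydrolase, genes: [scrB]}
  Trehalose:
    groups:
      - {name: trehalose_PTS, transporter: true, genes: [treB]}
      - {name: trehalose6P_hydrolase, genes: [treC]}
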