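# pestrisk reference table v1: demo product / active-ingredient database (16 entries)
# Row 1 (KILLER/ACTIVOL) is the published worked-exercise product; all DEMO-*
# entries are synthetic and correspond to no real authorization record.
product_name,ai_name,formulation,concentration_pct,gap_g_per_ha,aoel_mg_per_kg,dermal_absorption_pct
KILLER,ACTIVOL,powder,50,100,0.05,5
DEMO-LIQUIDA 10,DEMO-AI-01,liquid_concentrate,10,2000,0.1,10
DEMO-LIQUIDA 45,DEMO-AI-02,liquid_concentrate,45,1500,0.02,25
DEMO-LIQUIDA 75,DEMO-AI-03,liquid_concentrate,75,800,0.005,10
DEMO-LIQUIDA 95,DEMO-AI-04,liquid_concentrate,95,500,0.5,2
DEMO-POLVERE 20,DEMO-AI-05,powder,20,3000,0.01,10
DEMO-POLVERE 65,DEMO-AI-06,powder,65,400,0.001,50
DEMO-POLVERE 90,DEMO-AI-07,powder,90,250,1,1
DEMO-GRANULI 30,DEMO-AI-08,soluble_granule,30,1200,0.05,8
DEMO-GRANULI 80,DEMO-AI-09,soluble_granule,80,600,0.002,30
DEMO-BUSTE 25,DEMO-AI-10,soluble_bag,25,1000,0.02,15
DEMO-BUSTE 50,DEMO-AI-11,soluble_bag,50,700,0.3,5
DEMO-ERBICIDA,DEMO-AI-12,liquid_concentrate,36,4000,0.1,3
DEMO-FUNGICIDA,DEMO-AI-13,powder,80,2000,0.025,10
DEMO-INSETTICIDA,DEMO-AI-14,liquid_concentrate,25,300,0.005,40
DEMO-ACARICIDA,DEMO-AI-15,soluble_granule,55,900,0.015,20
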