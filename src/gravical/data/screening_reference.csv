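solvent,liquid_class,target_volume,mean_volume,min_volume,max_volume,dev_pct,cv_pct
AP,water,300,291.7,290.7,293.7,-2.76,0.31
AP,serum,300,295.4,294.6,296.6,-1.54,0.23
AP,DMSO,300,298.5,296.6,299.5,-0.49,0.35
AP,ethanol,300,298.9,296.6,300.5,-0.37,0.46
AP,liquid-system,300,288.9,287.8,289.8,-3.70,0.28
sucrose,water,300,287.4,285.7,289.1,-4.20,0.35
sucrose,serum,300,292.6,290.8,294.1,-2.45,0.37
sucrose,DMSO,300,294.6,294.1,295.8,-1.79,0.21
sucrose,ethanol,300,296.6,295.8,297.5,-1.12,0.21
sucrose,liquid-system,300,284.1,282.4,285.7,-5.29,0.37
beta-casein,water,300,297.7,295.7,299.9,-0.75,0.48
beta-casein,serum,300,301.3,299.6,302.6,0.45,0.41
beta-casein,DMSO,300,305.4,303.6,307.1,1.81,0.43
beta-casein,ethanol,300,305.2,303.4,306.6,1.74,0.38
beta-casein,liquid-system,300,287.0,283.5,289.9,-4.33,0.72
PBS,water,300,298.5,297.1,300.0,-0.49,0.30
PBS,serum,300,302.1,300.0,303.9,0.69,0.40
PBS,DMSO,300,305.3,303.9,306.9,1.76,0.34
PBS,ethanol,300,305.8,302.9,308.8,1.92,0.58
PBS,liquid-system,300,291.3,286.3,298.0,-2.90,1.56
AH,water,300,291.5,290.8,291.7,-2.83,0.16
AH,serum,300,296.9,295.7,297.6,-1.03,0.29
AH,DMSO,300,299.2,297.6,300.6,-0.25,0.35
AH,ethanol,300,300.6,299.6,301.6,0.20,0.30
AH,liquid-system,300,289.3,287.8,290.8,-3.57,0.36
NaCl,water,300,292.1,290.2,292.7,-2.65,0.30
NaCl,serum,300,295.9,294.4,296.9,-1.35,0.32
NaCl,DMSO,300,299.2,297.7,300.3,-0.27,0.29
NaCl,ethanol,300,298.9,297.7,299.4,-0.37,0.21
NaCl,liquid-system,300,286.6,285.1,287.6,-4.47,0.38
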