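 0.3120350014 -0.9487727474  0.0496430431
-0.9106184074  0.4051743585  0.0812887156
 0.9257942843  0.3694969484  0.0798557969
-0.2019001316 -0.9790978385 -0.0245715184
-0.1415642838  0.9150095400  0.3777791621
 0.6962861021 -0.6981496669  0.1666514528
-0.9711793890 -0.0256901386  0.2369612020
 0.6334049563  0.7735090215  0.0219534747
-0.0109788077 -0.9207076903  0.3900984681
-0.5967199882  0.7393916916  0.3118095285
 0.9640167313 -0.0661462401  0.2574809055
-0.7890395695 -0.5014175774  0.3549605201
 0.3718131767  0.8212196392  0.4328432347
 0.4018470951 -0.7532653082  0.5206825210
-0.7729333679  0.3335225339  0.5397561748
 0.7355835502  0.5058812404  0.4505563353
-0.4368165859 -0.7853299859  0.4386890512
 0.0251374928  0.6833901624  0.7296204441
 0.7610731450 -0.3883823424  0.5195448239
-0.7606224673 -0.1319714492  0.6356390476
 0.4217306638  0.4533496471  0.7852498613
-0.0214784969 -0.6392964379  0.7686603532
-0.4127874535  0.5604057698  0.7180194227
 0.7518205965  0.0762278629  0.6549466418
-0.4499438051 -0.4392857725  0.7775465146
-0.0420028674  0.2800365915  0.9590700009
 0.4008971568 -0.3996977371  0.8243319651
-0.4554565465  0.0907644115  0.8856190806
 0.3671557896  0.0239828449  0.9298502295
-0.0648391783 -0.2090675874  0.9757492633
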