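tract,FA,MD,AD,RD
Middle cerebellar peduncle,-3.4018,-4.0506,-4.0163,-2.7544
Pontine crossing tract,-6.6466,-8.9053,-9.0168,-5.5758
Genu of corpus callosum,-4.9810,-2.5437,-4.3934,-0.2206
Body of corpus callosum,-5.2457,-5.2061,-6.3880,-2.8863
Splenium of corpus callosum,-5.9731,-2.0907,-3.3389,0.0200
Fornix column and body,-4.1631,-1.5109,-3.5530,-0.5755
Corticospinal tract R,-7.7230,-8.4044,-7.1084,-5.4109
Corticospinal tract L,-8.7662,-8.5642,-8.3372,-5.0024
Medial lemniscus R,-9.8877,-7.8712,-10.0378,-3.0974
Medial lemniscus L,-8.8790,-5.7711,-8.9807,-0.8470
Inferior cerebellar peduncle R,-5.0904,-6.6215,-6.7659,-3.7108
Inferior cerebellar peduncle L,-3.7371,-3.9592,-4.2853,-1.7199
Superior cerebellar peduncle R,-6.9633,-4.1469,-6.7603,-1.3358
Superior cerebellar peduncle L,-8.9701,-6.6437,-9.4621,-2.8499
Cerebral peduncle R,-3.3242,-2.0068,-2.5099,-1.0224
Cerebral peduncle L,-3.5772,-2.2949,-2.7799,-1.1616
Anterior limb of internal capsule R,-4.3299,-5.5304,-5.6379,-3.6174
Anterior limb of internal capsule L,-3.6725,-4.9074,-4.9110,-3.3819
Posterior limb of internal capsule R,-6.5597,-6.5569,-6.1456,-4.0476
Posterior limb of internal capsule L,-6.4132,-5.1651,-5.0180,-3.2335
Retrolenticular part of internal capsule R,-6.5514,-7.7027,-6.6092,-5.2280
Retrolenticular part of internal capsule L,-7.0747,-8.7158,-7.6847,-5.5576
Anterior corona radiata R,-4.5589,-8.8317,-7.8856,-5.4455
Anterior corona radiata L,-4.7811,-8.1271,-8.2151,-5.2371
Superior corona radiata R,-6.8129,-10.7517,-9.0758,-7.7300
Superior corona radiata L,-7.6792,-10.5439,-9.2313,-7.3002
Posterior corona radiata R,-6.4174,-7.8086,-7.4006,-4.8591
Posterior corona radiata L,-5.9540,-8.0524,-7.3467,-5.5202
Posterior thalamic radiation R,-5.4262,-6.0225,-6.3447,-2.4691
Posterior thalamic radiation L,-6.2763,-7.1591,-7.6127,-3.7201
Sagittal stratum R,-3.8284,-4.4550,-4.1065,-2.1423
Sagittal stratum L,-4.4256,-6.1629,-5.4333,-3.8201
External capsule R,-7.0704,-10.6353,-10.3743,-6.8906
External capsule L,-6.8178,-10.9676,-10.8314,-7.2717
Cingulum cingulate gyrus R,-5.9627,-9.6954,-8.8075,-5.8706
Cingulum cingulate gyrus L,-6.0431,-9.9685,-8.6000,-5.4554
Cingulum hippocampus R,-2.6142,-4.6596,-4.0533,-2.5982
Cingulum hippocampus L,-2.3326,-4.2916,-3.9027,-2.6500
Fornix stria terminalis R,-8.0366,-9.1615,-8.4146,-6.9321
Fornix stria terminalis L,-8.0298,-7.8311,-7.6017,-5.3612
Superior longitudinal fasciculus R,-4.6390,-7.9398,-6.6292,-5.0616
Superior longitudinal fasciculus L,-5.7910,-9.2725,-8.2051,-5.8536
Superior fronto-occipital fasciculus R,-10.7480,-14.2809,-14.9662,-9.7102
Superior fronto-occipital fasciculus L,-9.9689,-12.5544,-12.9125,-9.0290
Uncinate fasciculus R,-5.6202,-8.1407,-9.2492,-4.4650
Uncinate fasciculus L,-5.8443,-9.4649,-9.6659,-4.8008
Tapetum R,-6.4361,-3.3919,-4.7050,-1.6238
Tapetum L,-4.6967,-3.4286,-4.1642,-2.1785
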