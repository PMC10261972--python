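species,measurement_time,moist_pct,mass_mean_g,mass_sd_g
centrale,0h,91.6,525,125.7
centrale,24h,90.3,462.2,131.1
centrale,48h,89.2,419.2,132.8
centrale,1week,74.3,190.5,96.6
centrale,dry,0,43.3,8.2
girgensohnii,0h,87.1,371.2,66.2
girgensohnii,24h,85.2,325.3,63.5
girgensohnii,48h,81.5,261.7,58.8
girgensohnii,1week,49.3,98,28.6
girgensohnii,dry,0,47.6,6.5
riparium,0h,88.9,422.5,73.6
riparium,24h,87.2,366.9,66.6
riparium,48h,83.8,291.7,60.2
riparium,1week,64.4,136.9,38.4
riparium,dry,0,46.2,6
capillifolium,0h,89.9,616,165.6
capillifolium,24h,88.4,541.1,159.8
capillifolium,48h,87.4,508.6,164.9
capillifolium,1week,73.1,258.1,123.9
capillifolium,dry,0,60.8,11.3
fallax,0h,91.6,588.2,152.7
fallax,24h,90.5,523.8,150.5
fallax,48h,88.7,449.7,153.5
fallax,1week,73.9,208.2,96.9
fallax,dry,0,48.3,8.6
angustifolium,0h,90.3,763.4,176.9
angustifolium,24h,89.5,712.6,180.2
angustifolium,48h,88.2,638.3,184
angustifolium,1week,80.9,406.5,150.7
angustifolium,dry,0,72.2,9.7
cuspidatum,0h,98.7,2646,155.6
cuspidatum,24h,98.6,2527.4,173.6
cuspidatum,48h,98.6,2507.8,161.4
cuspidatum,1week,98.4,2242.9,136.6
cuspidatum,dry,0,35.1,9.4
fuscum,0h,92.6,1119.4,163.5
fuscum,24h,91.9,1026.4,158.4
fuscum,48h,91.6,991.8,159.8
fuscum,1week,87.4,677.9,148.1
fuscum,dry,0,81.7,7.2
rubellum,0h,94.4,1611.7,286.2
rubellum,24h,94,1512.4,273.6
rubellum,48h,93.8,1476.8,278.7
rubellum,1week,92.2,1193.3,289
rubellum,dry,0,88.3,6.3
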