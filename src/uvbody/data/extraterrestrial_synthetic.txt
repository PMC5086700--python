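# Synthetic extraterrestrial solar spectral irradiance, mW m^-2 nm^-1.
# Deterministic analytic surrogate (diluted 5778 K blackbody); absolute
# values are not calibration targets, only spectral shape and closures.
# wavelength_nm value
250.0000 3.91775612e+02
251.0000 3.99579943e+02
252.0000 4.07443767e+02
253.0000 4.15365808e+02
254.0000 4.23344772e+02
255.0000 4.31379354e+02
256.0000 4.39468239e+02
257.0000 4.47610099e+02
258.0000 4.55803595e+02
259.0000 4.64047381e+02
260.0000 4.72340100e+02
261.0000 4.80680389e+02
262.0000 4.89066876e+02
263.0000 4.97498184e+02
264.0000 5.05972929e+02
265.0000 5.14489723e+02
266.0000 5.23047174e+02
267.0000 5.31643884e+02
268.0000 5.40278456e+02
269.0000 5.48949488e+02
270.0000 5.57655576e+02
271.0000 5.66395316e+02
272.0000 5.75167305e+02
273.0000 5.83970138e+02
274.0000 5.92802411e+02
275.0000 6.01662724e+02
276.0000 6.10549677e+02
277.0000 6.19461873e+02
278.0000 6.28397917e+02
279.0000 6.37356420e+02
280.0000 6.46335996e+02
281.0000 6.55335263e+02
282.0000 6.64352846e+02
283.0000 6.73387374e+02
284.0000 6.82437484e+02
285.0000 6.91501817e+02
286.0000 7.00579024e+02
287.0000 7.09667761e+02
288.0000 7.18766694e+02
289.0000 7.27874496e+02
290.0000 7.36989849e+02
291.0000 7.46111445e+02
292.0000 7.55237982e+02
293.0000 7.64368173e+02
294.0000 7.73500737e+02
295.0000 7.82634406e+02
296.0000 7.91767920e+02
297.0000 8.00900033e+02
298.0000 8.10029509e+02
299.0000 8.19155123e+02
300.0000 8.28275662e+02
301.0000 8.37389927e+02
302.0000 8.46496729e+02
303.0000 8.55594892e+02
304.0000 8.64683255e+02
305.0000 8.73760666e+02
306.0000 8.82825991e+02
307.0000 8.91878105e+02
308.0000 9.00915899e+02
309.0000 9.09938277e+02
310.0000 9.18944158e+02
311.0000 9.27932472e+02
312.0000 9.36902167e+02
313.0000 9.45852202e+02
314.0000 9.54781553e+02
315.0000 9.63689208e+02
316.0000 9.72574172e+02
317.0000 9.81435462e+02
318.0000 9.90272112e+02
319.0000 9.99083170e+02
320.0000 1.00786770e+03
321.0000 1.01662478e+03
322.0000 1.02535350e+03
323.0000 1.03405296e+03
324.0000 1.04272230e+03
325.0000 1.05136065e+03
326.0000 1.05996717e+03
327.0000 1.06854101e+03
328.0000 1.07708136e+03
329.0000 1.08558743e+03
330.0000 1.09405842e+03
331.0000 1.10249357e+03
332.0000 1.11089211e+03
333.0000 1.11925331e+03
334.0000 1.12757644e+03
335.0000 1.13586078e+03
336.0000 1.14410564e+03
337.0000 1.15231034e+03
338.0000 1.16047422e+03
339.0000 1.16859661e+03
340.0000 1.17667688e+03
341.0000 1.18471440e+03
342.0000 1.19270858e+03
343.0000 1.20065881e+03
344.0000 1.20856451e+03
345.0000 1.21642513e+03
346.0000 1.22424010e+03
347.0000 1.23200890e+03
348.0000 1.23973099e+03
349.0000 1.24740587e+03
350.0000 1.25503304e+03
351.0000 1.26261203e+03
352.0000 1.27014236e+03
353.0000 1.27762358e+03
354.0000 1.28505525e+03
355.0000 1.29243694e+03
356.0000 1.29976824e+03
357.0000 1.30704874e+03
358.0000 1.31427806e+03
359.0000 1.32145582e+03
360.0000 1.32858165e+03
361.0000 1.33565522e+03
362.0000 1.34267618e+03
363.0000 1.34964420e+03
364.0000 1.35655897e+03
365.0000 1.36342019e+03
366.0000 1.37022758e+03
367.0000 1.37698085e+03
368.0000 1.38367973e+03
369.0000 1.39032398e+03
370.0000 1.39691335e+03
371.0000 1.40344760e+03
372.0000 1.40992653e+03
373.0000 1.41634992e+03
374.0000 1.42271756e+03
375.0000 1.42902928e+03
376.0000 1.43528489e+03
377.0000 1.44148424e+03
378.0000 1.44762715e+03
379.0000 1.45371349e+03
380.0000 1.45974312e+03
381.0000 1.46571591e+03
382.0000 1.47163175e+03
383.0000 1.47749053e+03
384.0000 1.48329215e+03
385.0000 1.48903653e+03
386.0000 1.49472357e+03
387.0000 1.50035323e+03
388.0000 1.50592542e+03
389.0000 1.51144011e+03
390.0000 1.51689724e+03
391.0000 1.52229679e+03
392.0000 1.52763872e+03
393.0000 1.53292301e+03
394.0000 1.53814966e+03
395.0000 1.54331867e+03
396.0000 1.54843003e+03
397.0000 1.55348377e+03
398.0000 1.55847990e+03
399.0000 1.56341844e+03
400.0000 1.56829944e+03
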