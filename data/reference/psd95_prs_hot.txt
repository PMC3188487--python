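# PSD-95 PDZ3: published hot-residue list (χ > 1.0) from the perturbation
# response scan of the apo crystal structure, author numbering.
314
316
326
327
328
329
330
335
336
337
338
339
340
341
345
346
347
353
354
355
356
358
359
361
362
367
370
372
375
379
386
387
388
389
390
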